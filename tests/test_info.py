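"""MDL discretization, plug-in information estimates and the comparator criteria."""

import numpy as np
import pytest

from resi import (
    MICache,
    MutualInfoSelector,
    NoRelevantFeaturesError,
    cfs_merit,
    cmim_score,
    conditional_mutual_information,
    entropy_bits,
    greedy_select,
    if_score,
    mdl_discretize,
    mutual_information,
    symmetrical_uncertainty,
)
from resi.info import CRITERIA, _greedy_mi


class TestMdlDiscretize:
    def test_clean_separation_yields_single_cut(self):
        d = mdl_discretize([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert d.cut_points.size == 1
        assert 3 < d.cut_points[0] < 10
        assert d.bins.tolist() == [0, 0, 0, 1, 1, 1]

    def test_homogeneous_labels_no_cut(self):
        d = mdl_discretize([1, 5, 2, 9], [0, 0, 0, 0])
        assert d.cut_points.size == 0
        assert d.bins.tolist() == [0, 0, 0, 0]

    def test_constant_feature_no_cut(self):
        d = mdl_discretize([3, 3, 3, 3], [0, 1, 0, 1])
        assert d.cut_points.size == 0

    def test_weak_split_rejected_by_mdl(self):
        # a single-swap pattern at n=8 never justifies the coding cost
        d = mdl_discretize([1, 2, 3, 4, 5, 6, 7, 8], [0, 1, 0, 1, 0, 1, 0, 1])
        assert d.cut_points.size == 0

    def test_two_cuts_for_three_blocks(self):
        # blocks of 16 make both recursive splits pass the MDL cost
        values = np.concatenate([np.arange(16), np.arange(16) + 100, np.arange(16) + 200])
        labels = np.array([0] * 16 + [1] * 16 + [0] * 16)
        d = mdl_discretize(values, labels)
        assert d.cut_points.size == 2
        assert np.array_equal(np.unique(d.bins), [0, 1, 2])

    def test_apply_thresholds_new_values_consistently(self):
        d = mdl_discretize([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        cut = d.cut_points[0]
        assert d.apply([0.0, cut, cut + 1e-9, 100.0]).tolist() == [0, 0, 1, 1]


class TestInformationEstimates:
    def test_perfect_dependence_is_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_independent_uniform_pair_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_self_information_equals_entropy(self, rng):
        a = rng.integers(0, 3, 30)
        assert mutual_information(a, a) == pytest.approx(entropy_bits(a))

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 25)
            b = rng.integers(0, 4, 25)
            assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-12)
            assert mutual_information(a, b) >= -1e-12

    def test_relevance_bounded_by_label_entropy(self, rng):
        y = rng.integers(0, 2, 40)
        hy = entropy_bits(y)
        for _ in range(10):
            a = rng.integers(0, 5, 40)
            assert mutual_information(a, y) <= hy + 1e-12

    def test_cmi_within_class_independence_is_zero(self):
        y = np.array([0] * 4 + [1] * 4)
        a = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        b = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert conditional_mutual_information(a, b, y) == pytest.approx(0.0)

    def test_cmi_constant_label_reduces_to_mi(self, rng):
        a = rng.integers(0, 2, 20)
        b = rng.integers(0, 2, 20)
        y = np.zeros(20, dtype=int)
        assert conditional_mutual_information(a, b, y) == pytest.approx(
            mutual_information(a, b)
        )

    def test_xor_structure_has_conditional_but_no_marginal_information(self):
        # uniform a,b with y = a xor b: I(a;b)=0 yet I(a;b|y)=1 bit
        a = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        b = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        y = a ^ b
        assert mutual_information(a, b) == pytest.approx(0.0)
        assert conditional_mutual_information(a, b, y) == pytest.approx(1.0)


class TestGreedySelection:
    @pytest.fixture
    def duplicate_and_weak(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        d = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        e = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        return np.column_stack([d, d, e]).astype(float), y

    def test_mrmr_penalises_exact_duplicate(self, duplicate_and_weak):
        X, y = duplicate_and_weak
        sel = MutualInfoSelector(criterion="mrmr", max_features=2, discretize=False).fit(X, y)
        assert sel.ranking_.tolist() == [0, 2]

    def test_mrmr_step2_merits_match_brute_force(self, duplicate_and_weak):
        X, y = duplicate_and_weak
        codes = X.astype(int)
        cache = MICache(codes, y)
        seed = int(np.argmax(cache.relevance))
        merits = {p: cache.relevance[p] - cache.mi(p, seed) for p in (1, 2)}
        sel = MutualInfoSelector(criterion="mrmr", max_features=2, discretize=False).fit(X, y)
        assert sel.merits_[1] == pytest.approx(max(merits.values()))

    def test_single_feature_selected_regardless_of_criterion(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        X = np.array([[0, 0, 1, 1, 0, 1]], dtype=float).T
        for crit in CRITERIA:
            beta = 1.0 if crit in ("mifs", "mifsu") else None
            sel = MutualInfoSelector(
                criterion=crit, beta=beta, max_features=1, discretize=False
            ).fit(X, y)
            assert sel.ranking_.tolist() == [0]

    def test_no_informative_feature_raises(self):
        y = np.array([0, 0, 1, 1])
        X = np.zeros((4, 3))
        with pytest.raises(NoRelevantFeaturesError):
            MutualInfoSelector(criterion="mrmr", discretize=False).fit(X, y)

    def test_beta_required_for_mifs_family(self, duplicate_and_weak):
        X, y = duplicate_and_weak
        for crit in ("mifs", "mifsu"):
            with pytest.raises(ValueError, match="beta"):
                MutualInfoSelector(criterion=crit, discretize=False).fit(X, y)

    def test_continuous_input_discretized_before_selection(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 20)
        strong = np.where(y == 1, 5.0, 0.0) + rng.normal(0, 0.3, 40)
        noise = rng.normal(size=40)
        X = np.column_stack([noise, strong])
        sel = MutualInfoSelector(criterion="mrmr", max_features=1).fit(X, y)
        assert sel.ranking_.tolist() == [1]
        assert sel.discretizers_[1].cut_points.size >= 1

    def test_dataset_wrapper_returns_feature_ids(self):
        from resi import ExpressionDataset

        rng = np.random.default_rng(2)
        y = np.repeat(["a", "b"], 12)
        strong = np.where(y == "a", 0.0, 6.0) + rng.normal(0, 0.2, 24)
        ds = ExpressionDataset(
            values=np.column_stack([rng.normal(size=24), strong]),
            labels=y,
            feature_ids=["noise", "marker"],
            instance_ids=[f"s{i}" for i in range(24)],
        )
        res = greedy_select(ds, "mrmr", max_features=2)
        assert res.feature_ids[0] == "marker"


def _random_discrete_problem(rng, n=30, m=6):
    y = rng.integers(0, 2, n)
    X = np.column_stack(
        [np.where(rng.random(n) < 0.35, rng.integers(0, 2, n), y) for _ in range(m)]
    )
    return X, y


class TestCriterionEquivalences:
    def test_cmim_equals_informative_fragments(self, rng):
        """CMIM and IF are the same score via the MI chain rule."""
        for _ in range(30):
            X, y = _random_discrete_problem(rng)
            cache = MICache(X, y)
            selected = list(rng.choice(X.shape[1], size=rng.integers(1, 4), replace=False))
            p = int(rng.choice([j for j in range(X.shape[1]) if j not in selected]))
            assert cmim_score(p, selected, cache) == pytest.approx(
                if_score(p, selected, cache), abs=1e-9
            )

    def test_mimr_and_jmi_produce_identical_orders(self, rng):
        for _ in range(15):
            X, y = _random_discrete_problem(rng)
            a, _, _ = _greedy_mi(X, y, "mimr", None, X.shape[1])
            b, _, _ = _greedy_mi(X, y, "jmi", None, X.shape[1])
            assert a == b

    def test_mrmr_is_mifs_with_step_dependent_beta(self, rng):
        for _ in range(15):
            X, y = _random_discrete_problem(rng)
            cache = MICache(X, y)
            selected = list(rng.choice(X.shape[1], size=rng.integers(1, 5), replace=False))
            p = int(rng.choice([j for j in range(X.shape[1]) if j not in selected]))
            assert CRITERIA["mrmr"](p, selected, cache) == pytest.approx(
                CRITERIA["mifs"](p, selected, cache, 1 / len(selected)), abs=1e-12
            )


class TestCfsMerit:
    def test_single_feature_reduces_to_su_with_label(self, rng):
        y = rng.integers(0, 2, 30)
        X = np.column_stack([y, rng.integers(0, 2, 30)])
        cache = MICache(X, y)
        assert cfs_merit([0], cache) == pytest.approx(
            symmetrical_uncertainty(X[:, 0], y)
        )

    def test_duplicate_feature_adds_no_merit(self):
        # with r_ff = 1 the subset merit k*r/sqrt(k + k(k-1)) collapses to r:
        # a fully redundant copy can never improve a CFS subset
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        f = np.array([0, 0, 1, 1, 1, 1, 0, 1])
        X = np.column_stack([f, f])
        cache = MICache(X, y)
        assert cfs_merit([0, 1], cache) == pytest.approx(cfs_merit([0], cache))

    def test_complementary_feature_beats_duplicate(self):
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        f = np.array([0, 0, 1, 1, 0, 0, 1, 0])   # partial predictor
        g = np.array([0, 1, 1, 1, 0, 0, 1, 1])   # different partial predictor
        X = np.column_stack([f, f, g])
        cache = MICache(X, y)
        assert cfs_merit([0, 2], cache) > cfs_merit([0, 1], cache)

    def test_uninformative_single_feature_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        X = np.array([[0, 1, 0, 1]]).T
        cache = MICache(X, y)
        assert cfs_merit([0], cache) == pytest.approx(0.0)

    def test_empty_subset_rejected(self, rng):
        cache = MICache(rng.integers(0, 2, (10, 2)), rng.integers(0, 2, 10))
        with pytest.raises(ValueError):
            cfs_merit([], cache)
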
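"""Mutual-information comparator criteria and MDL discretization.

This module hosts the classical redundancy-aware forward-selection family
that RESI is benchmarked against: MIFS, mRMR, MIFS-U, mIMR/JMI and CMIM/IF,
all expressed as merit functions over plug-in mutual-information estimates on
discretized features, plus the CFS subset merit.  Continuous features are
discretized with the Fayyad–Irani recursive entropy-minimisation procedure
under the MDL stopping criterion; a feature for which no cut is accepted
carries no information about the label and is treated as irrelevant.

All information quantities are in bits.  The base only rescales every merit
uniformly and never changes a selection order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data

from ._exceptions import NoRelevantFeaturesError
from .selection import SelectionResult, _binarize_labels, _RankedSelectorBase

__all__ = [
    "DiscretizedFeature",
    "mdl_discretize",
    "entropy_bits",
    "mutual_information",
    "conditional_mutual_information",
    "symmetrical_uncertainty",
    "MICache",
    "cmim_score",
    "if_score",
    "cfs_merit",
    "MutualInfoSelector",
    "greedy_select",
    "CRITERIA",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# MDL discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizedFeature:
    """Cut points and the induced integer codes of one feature.

    ``bins[u]`` equals the number of cut points strictly below the value, so
    bins are right-closed: a value equal to a cut point falls in the lower
    bin.  No accepted cut leaves ``cut_points`` empty and every code 0.
    """

    cut_points: np.ndarray
    bins: np.ndarray

    def apply(self, values):
        """Code new values by thresholding with the fitted cut points."""
        return np.searchsorted(self.cut_points, np.asarray(values, dtype=float), side="left")


def _label_entropy(y):
    _, counts = np.unique(y, return_counts=True)
    return float(_scipy_entropy(counts, base=2))


def _fayyad_irani(values, labels, cuts):
    """Recursively split sorted (values, labels), appending accepted cuts."""
    n = values.shape[0]
    if n < 2:
        return
    ent_s = _label_entropy(labels)
    if ent_s == 0.0:
        return
    # candidate boundaries between adjacent distinct values whose label
    # composition differs (boundary points in Fayyad's sense)
    change = np.flatnonzero(values[1:] > values[:-1]) + 1  # group starts
    best_gain, best_pos, best_stats = -np.inf, None, None
    for pos in change:
        left_y, right_y = labels[:pos], labels[pos:]
        # skip non-boundaries: both sides pure with the same single label
        ent_l = _label_entropy(left_y)
        ent_r = _label_entropy(right_y)
        if ent_l == 0.0 and ent_r == 0.0 and left_y[0] == right_y[0]:
            continue
        gain = ent_s - (pos * ent_l + (n - pos) * ent_r) / n
        if gain > best_gain:
            best_gain, best_pos = gain, pos
            best_stats = (ent_l, ent_r)
    if best_pos is None:
        return
    ent_l, ent_r = best_stats
    k = np.unique(labels).size
    k1 = np.unique(labels[:best_pos]).size
    k2 = np.unique(labels[best_pos:]).size
    delta = np.log2(3**k - 2) - (k * ent_s - k1 * ent_l - k2 * ent_r)
    if best_gain <= (np.log2(n - 1) + delta) / n:
        return
    cut = (values[best_pos - 1] + values[best_pos]) / 2.0
    cuts.append(cut)
    _fayyad_irani(values[:best_pos], labels[:best_pos], cuts)
    _fayyad_irani(values[best_pos:], labels[best_pos:], cuts)


def mdl_discretize(feature_values, labels):
    """Supervised discretization by recursive entropy minimisation with the
    MDL acceptance rule.

    A boundary is accepted only when its information gain exceeds
    ``(log2(n-1) + delta) / n`` with the usual three-way coding term delta;
    candidate cuts are midpoints between adjacent distinct values whose label
    composition differs.  Returns an empty cut list (single bin) when no
    split is justified, e.g. for label-homogeneous or constant features.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 instances to discretize")
    order = np.argsort(x, kind="stable")
    cuts: list = []
    _fayyad_irani(x[order], y[order], cuts)
    cut_points = np.sort(np.asarray(cuts, dtype=float))
    bins = np.searchsorted(cut_points, x, side="left")
    return DiscretizedFeature(cut_points=cut_points, bins=bins)


# ---------------------------------------------------------------------------
# plug-in information estimates (bits)
# ---------------------------------------------------------------------------

def entropy_bits(codes):
    """Empirical entropy of a discrete code vector, in bits."""
    _, counts = np.unique(np.asarray(codes), return_counts=True)
    return float(_scipy_entropy(counts, base=2))


def mutual_information(a, b):
    """Plug-in mutual information of two discrete code vectors, in bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("code vectors differ in length")
    return float(mutual_info_score(a, b)) / _LN2


def conditional_mutual_information(a, b, y):
    """I(a; b | y): class-weighted plug-in MI within each label stratum, bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    y = np.asarray(y)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("code vectors differ in length")
    total = 0.0
    n = y.shape[0]
    for cls in np.unique(y):
        idx = y == cls
        total += idx.sum() / n * (float(mutual_info_score(a[idx], b[idx])) / _LN2)
    return total


def symmetrical_uncertainty(a, b):
    """SU(a, b) = 2 I(a;b) / (H(a) + H(b)); 0 when both entropies vanish."""
    ha, hb = entropy_bits(a), entropy_bits(b)
    if ha + hb == 0.0:
        return 0.0
    return 2.0 * mutual_information(a, b) / (ha + hb)


class MICache:
    """Memoised information quantities over a matrix of discrete codes.

    Relevance I(X_i;Y) and entropies are computed eagerly (cheap, needed by
    every criterion); pairwise, conditional and joint terms on demand.
    """

    def __init__(self, codes, y):
        self.codes = np.asarray(codes)
        self.y = np.asarray(y)
        m = self.codes.shape[1]
        self.relevance = np.array(
            [mutual_information(self.codes[:, j], self.y) for j in range(m)]
        )
        self.entropy = np.array([entropy_bits(self.codes[:, j]) for j in range(m)])
        self._pair: dict = {}
        self._cond: dict = {}
        self._joint_y: dict = {}

    def mi(self, i, j):
        key = (min(i, j), max(i, j))
        if key not in self._pair:
            self._pair[key] = mutual_information(self.codes[:, i], self.codes[:, j])
        return self._pair[key]

    def cmi(self, i, j):
        """I(X_i; X_j | Y)."""
        key = (min(i, j), max(i, j))
        if key not in self._cond:
            self._cond[key] = conditional_mutual_information(
                self.codes[:, i], self.codes[:, j], self.y
            )
        return self._cond[key]

    def joint_mi_with_y(self, i, j):
        """I(X_i, X_j; Y): MI of the paired variable with the label."""
        key = (min(i, j), max(i, j))
        if key not in self._joint_y:
            a = self.codes[:, i].astype(np.int64)
            b = self.codes[:, j].astype(np.int64)
            paired = a * (b.max() + 1) + b
            self._joint_y[key] = mutual_information(paired, self.y)
        return self._joint_y[key]

    def su_with_label(self, i):
        return symmetrical_uncertainty(self.codes[:, i], self.y)


# ---------------------------------------------------------------------------
# merit functions
# ---------------------------------------------------------------------------

def _merit_mifs(p, selected, cache, beta):
    return cache.relevance[p] - beta * sum(cache.mi(p, i) for i in selected)

def _merit_mrmr(p, selected, cache, beta=None):
    return cache.relevance[p] - sum(cache.mi(p, i) for i in selected) / len(selected)

def _merit_mifsu(p, selected, cache, beta):
    penalty = 0.0
    for i in selected:
        if cache.entropy[i] > 0:
            penalty += cache.relevance[i] / cache.entropy[i] * cache.mi(p, i)
    return cache.relevance[p] - beta * penalty

def _merit_mimr(p, selected, cache, beta=None):
    interaction = sum(cache.mi(p, i) - cache.cmi(p, i) for i in selected)
    return cache.relevance[p] - interaction / len(selected)

def _merit_jmi(p, selected, cache, beta=None):
    return sum(cache.joint_mi_with_y(p, i) for i in selected) / len(selected)

def cmim_score(p, selected, cache, beta=None):
    """CMIM merit: I(X_p;Y) minus the worst-case redundancy max_i [I - I|Y]."""
    return cache.relevance[p] - max(cache.mi(p, i) - cache.cmi(p, i) for i in selected)

def if_score(p, selected, cache):
    """Informative-Fragments score min_i [I(X_p, X_i; Y) - I(X_i; Y)].

    By the chain rule this equals min_i I(X_p; Y | X_i) and therefore agrees
    with :func:`cmim_score`; both are kept so the equivalence can be checked
    numerically rather than assumed.
    """
    return min(cache.joint_mi_with_y(p, i) - cache.relevance[i] for i in selected)


CRITERIA = {
    "mifs": _merit_mifs,
    "mrmr": _merit_mrmr,
    "mifsu": _merit_mifsu,
    "mimr": _merit_mimr,
    "jmi": _merit_jmi,
    "cmim": cmim_score,
}

_NEEDS_BETA = {"mifs", "mifsu"}

# plug-in MI is mathematically >= 0; anything at or below this is float dust
# from a degenerate (single-bin) feature and counts as "no information"
_RELEVANCE_EPS = 1e-12


def cfs_merit(selected, cache):
    """CFS subset merit k r_cf / sqrt(k + k(k-1) r_ff).

    r_cf is the mean feature-label symmetrical uncertainty over the subset
    and r_ff the mean pairwise feature-feature SU.  For a single feature the
    merit reduces to SU(X;Y).
    """
    selected = list(selected)
    if not selected:
        raise ValueError("CFS merit requires a non-empty subset")
    k = len(selected)
    r_cf = np.mean([cache.su_with_label(i) for i in selected])
    if k == 1:
        return float(r_cf)
    pairs = [
        symmetrical_uncertainty(cache.codes[:, i], cache.codes[:, j])
        for idx, i in enumerate(selected)
        for j in selected[idx + 1:]
    ]
    r_ff = float(np.mean(pairs))
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


# ---------------------------------------------------------------------------
# greedy forward search
# ---------------------------------------------------------------------------

def _greedy_mi(codes, y, criterion, beta, max_features):
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    if criterion in _NEEDS_BETA and beta is None:
        raise ValueError(f"criterion {criterion!r} requires beta (no default)")
    cache = MICache(codes, y)
    candidates = np.flatnonzero(cache.relevance > _RELEVANCE_EPS)
    if candidates.size == 0:
        raise NoRelevantFeaturesError(
            "no feature carries information about the label "
            f"(max I(X;Y) = {cache.relevance.max():.6g} bits)",
            best_score=float(cache.relevance.max()),
        )
    merit_fn = CRITERIA[criterion]
    remaining = list(candidates)
    seed = int(candidates[np.argmax(cache.relevance[candidates])])
    order, merits = [seed], [float(cache.relevance[seed])]
    remaining.remove(seed)
    n_select = min(max_features, candidates.size)
    while len(order) < n_select and remaining:
        scores = np.array([merit_fn(p, order, cache, beta) for p in remaining])
        # merits reached via different float paths can differ by an ulp on
        # mathematically tied candidates; resolve near-ties to the lowest index
        best = int(np.flatnonzero(scores >= scores.max() - 1e-9)[0])
        order.append(remaining[best])
        merits.append(float(scores[best]))
        del remaining[best]
    return order, merits, cache


class MutualInfoSelector(_RankedSelectorBase):
    """Greedy forward selection under a mutual-information merit criterion.

    Parameters
    ----------
    criterion : {"mifs", "mrmr", "mifsu", "mimr", "jmi", "cmim"}
    beta : float or None
        Redundancy weight; required for "mifs" and "mifsu" (no default).
    max_features : int, default 80
    discretize : bool, default True
        Apply MDL discretization to continuous input.  Set False when the
        input already holds small integer codes.  Features without an
        accepted cut are treated as irrelevant.

    Attributes
    ----------
    ranking_, merits_ : selection order and per-step merit (bits).
    discretizers_ : per-feature :class:`DiscretizedFeature` (or None).
    n_removed_irrelevant_ : features excluded before the greedy loop.
    """

    def __init__(self, criterion="mrmr", beta=None, max_features=80, discretize=True):
        self.criterion = criterion
        self.beta = beta
        self.max_features = max_features
        self.discretize = discretize

    def _compute_ranking(self, X, y01):
        m = X.shape[1]
        if self.discretize:
            discretizers = [mdl_discretize(X[:, j], y01) for j in range(m)]
            codes = np.column_stack([d.bins for d in discretizers])
        else:
            discretizers = None
            codes = X.astype(np.int64)
        order, merits, cache = _greedy_mi(
            codes, y01, self.criterion, self.beta, self.max_features
        )
        n_irrelevant = int(m - np.count_nonzero(cache.relevance > _RELEVANCE_EPS))
        return np.asarray(order), np.asarray(merits), {
            "discretizers_": discretizers,
            "n_removed_irrelevant_": n_irrelevant,
        }


def greedy_select(ds, criterion, max_features=80, beta=None, discretize=True):
    """Greedy MI-criterion selection on an :class:`~resi.data.ExpressionDataset`."""
    sel = MutualInfoSelector(
        criterion=criterion, beta=beta, max_features=max_features, discretize=discretize
    ).fit(ds.values, ds.y01)
    return sel.selection_result(feature_ids=ds.feature_ids, method=criterion)
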
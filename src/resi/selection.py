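"""Forward feature selection estimators.

`RESISelector` implements the two-stage search: an irrelevance filter drops
every feature whose |t| falls below epsilon, the first feature is the |t|
maximiser, and each subsequent feature maximises J_REMI — the candidate's |t|
minus its mean instance-level redundancy (REMI) to the already selected
features.  `TStatisticSelector` is the pure |t|-ranking baseline.  Both are
scikit-learn selectors (``fit`` / ``transform`` / ``get_support``) and
compose with pipelines and model selection; :func:`resi_select` and
:func:`rank_by_t` are thin dataset-level wrappers.

Blur masks are computed once per surviving feature and reused throughout the
greedy loop, so selecting 80 features from a 60 x 2000 matrix takes seconds.
All tie-breaks go to the lower feature index; the algorithm is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from ._exceptions import NoRelevantFeaturesError
from .core import RESIParams, blur_count_threshold, purity_counts, t_statistics

__all__ = [
    "SelectionResult",
    "RESISelector",
    "TStatisticSelector",
    "resi_select",
    "rank_by_t",
]


@dataclass
class SelectionResult:
    """Ordered selection with per-step merit scores.

    ``merits[0]`` is the seed feature's |t|; later entries are the J_REMI (or
    criterion) merit at the step the feature was added.
    """

    selected: list
    merits: list
    feature_ids: list = None
    removed_irrelevant: int = 0
    method: str = ""
    params: dict = None

    def __post_init__(self):
        if len(self.selected) != len(self.merits):
            raise ValueError("selected and merits must have equal length")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")

    def to_dict(self):
        return {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "feature_ids": self.feature_ids,
            "merits": [float(v) for v in self.merits],
            "removed_irrelevant": int(self.removed_irrelevant),
            "params": self.params,
        }


def _binarize_labels(y):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected a binary target, found {classes.size} class level(s)")
    positive = classes[np.argmin(counts)]
    return (y == positive).astype(int), classes, positive


class _RankedSelectorBase(SelectorMixin, BaseEstimator):
    """Shared fit/transform plumbing for order-producing selectors."""

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, ensure_min_samples=4)
        y01, self.classes_, self.positive_class_ = _binarize_labels(y)
        self.ranking_, self.merits_, extras = self._compute_ranking(X, y01)
        for name, value in extras.items():
            setattr(self, name, value)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.ranking_] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selection_result(self, feature_ids=None, method=None):
        """Package the fitted ranking as a :class:`SelectionResult`."""
        check_is_fitted(self, "support_")
        return SelectionResult(
            selected=[int(i) for i in self.ranking_],
            merits=[float(v) for v in self.merits_],
            feature_ids=None
            if feature_ids is None
            else [feature_ids[i] for i in self.ranking_],
            removed_irrelevant=int(getattr(self, "n_removed_irrelevant_", 0)),
            method=method or type(self).__name__,
            params=self.get_params(),
        )

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class RESISelector(_RankedSelectorBase):
    """Redundant-feature selection depending on instances.

    Parameters
    ----------
    k : int, default 3
        Neighbourhood size for instance purity.
    mu : float, default 0.66
        Clear/blur purity threshold; purity <= mu is blur-discerned.
    epsilon : float, default 0.1
        Stage-1 irrelevance cutoff on |t|.  Note that |t| is computed on the
        data as given; standardize beforehand if your epsilon assumes it.
    max_features : int, default 80
        Stopping bound on the number of selected features.
    min_merit : float or None, default None
        Optional early stop when the best available J_REMI merit falls below
        this value; disabled by default.

    Attributes
    ----------
    ranking_ : ndarray — selected feature indices in selection order.
    merits_ : ndarray — per-step merit (|t| for the seed, J_REMI after).
    n_removed_irrelevant_ : int — features dropped by the epsilon filter.
    abs_t_ : ndarray of shape (m,) — |t| of every input feature.
    """

    def __init__(self, k=3, mu=0.66, epsilon=0.1, max_features=80, min_merit=None):
        self.k = k
        self.mu = mu
        self.epsilon = epsilon
        self.max_features = max_features
        self.min_merit = min_merit

    def _compute_ranking(self, X, y01):
        params = RESIParams(
            k=self.k,
            mu=self.mu,
            epsilon=self.epsilon,
            max_features=self.max_features,
            min_merit=self.min_merit,
        )
        abs_t = np.abs(t_statistics(X, y01))
        surviving = np.flatnonzero(abs_t >= params.epsilon)
        if surviving.size == 0:
            raise NoRelevantFeaturesError(
                f"all {X.shape[1]} features have |t| < epsilon={params.epsilon} "
                f"(max |t| observed: {abs_t.max():.6g})",
                best_score=float(abs_t.max()),
            )
        thresh = blur_count_threshold(params.k, params.mu)
        # purity/blur cache: one pass per surviving feature
        blur = np.empty((surviving.size, X.shape[0]), dtype=bool)
        for row, j in enumerate(surviving):
            blur[row] = purity_counts(X[:, j], y01, params.k) <= thresh
        blur_counts = blur.sum(axis=1)

        t_surv = abs_t[surviving]
        n_select = min(params.max_features, surviving.size)
        remaining = np.ones(surviving.size, dtype=bool)
        sum_remi = np.zeros(surviving.size)
        order, merits = [], []

        seed = int(np.argmax(t_surv))  # first occurrence -> lowest index
        order.append(seed)
        merits.append(float(t_surv[seed]))
        remaining[seed] = False

        while len(order) < n_select and remaining.any():
            s = order[-1]
            overlap = (blur & blur[s]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                step_remi = np.where(blur_counts > 0, overlap / np.maximum(blur_counts, 1), 0.0)
            sum_remi += step_remi
            merit = t_surv - sum_remi / len(order)
            masked = np.where(remaining, merit, -np.inf)
            best = int(np.argmax(masked))
            if params.min_merit is not None and masked[best] < params.min_merit:
                break
            order.append(best)
            merits.append(float(masked[best]))
            remaining[best] = False

        ranking = surviving[np.asarray(order)]
        return (
            ranking,
            np.asarray(merits),
            {
                "n_removed_irrelevant_": int(X.shape[1] - surviving.size),
                "abs_t_": abs_t,
            },
        )


class TStatisticSelector(_RankedSelectorBase):
    """Baseline ranking by decreasing |t|, ties to the lower feature index."""

    def __init__(self, max_features=80):
        self.max_features = max_features

    def _compute_ranking(self, X, y01):
        if self.max_features < 1:
            raise ValueError(f"max_features must be >= 1, got {self.max_features}")
        abs_t = np.abs(t_statistics(X, y01))
        # stable sort on -|t| keeps the lower index first among ties
        order = np.argsort(-abs_t, kind="stable")[: self.max_features]
        return order, abs_t[order], {"abs_t_": abs_t}


def resi_select(ds, params=None):
    """Run RESI on an :class:`~resi.data.ExpressionDataset`."""
    params = params or RESIParams()
    sel = RESISelector(
        k=params.k,
        mu=params.mu,
        epsilon=params.epsilon,
        max_features=params.max_features,
        min_merit=params.min_merit,
    ).fit(ds.values, ds.y01)
    return sel.selection_result(feature_ids=ds.feature_ids, method="resi")


def rank_by_t(ds, max_features=80):
    """Rank an :class:`~resi.data.ExpressionDataset`'s features by |t|."""
    sel = TStatisticSelector(max_features=max_features).fit(ds.values, ds.y01)
    return sel.selection_result(feature_ids=ds.feature_ids, method="ranking")
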
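"""Instance-level predictive-power and redundancy primitives.

The measures implemented here treat a feature's predictive power not as a
single score but as a *distribution over instances*: for every instance we ask
whether the feature, viewed through a k-nearest-neighbour lens on its own
axis, places the instance among same-class neighbours ("clear-discerned") or
not ("blur-discerned").  Redundancy between two features is then the overlap
of their blur sets (REMI), and a candidate feature's merit combines its
absolute two-sample t-statistic with the mean REMI to the already selected
features (J_REMI).

All functions are pure and operate on plain numpy arrays; the selection
estimators in :mod:`resi.selection` cache and vectorise around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._exceptions import InsufficientInstancesError

__all__ = [
    "neighborhood_purity",
    "purity_counts",
    "blur_count_threshold",
    "discern",
    "PurityProfile",
    "RESIParams",
    "remi",
    "t_statistic",
    "t_statistics",
    "j_remi",
]


def purity_counts(feature_values, labels, k):
    """Count same-class members among each instance's k nearest neighbours.

    Neighbourhoods are formed on the single feature axis with distance
    |x_v - x_u|; the instance itself is excluded, and distance ties are broken
    in favour of the lower instance index so the result is deterministic.

    Parameters
    ----------
    feature_values : array-like of shape (n,)
        Expression values of one feature.
    labels : array-like of shape (n,)
        Binary class labels (any comparable dtype).
    k : int
        Neighbourhood size; requires ``n >= k + 1``.

    Returns
    -------
    ndarray of shape (n,) of int
        For each instance, the number of its k nearest neighbours sharing its
        label (0..k).
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    n = x.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k:
        raise InsufficientInstancesError(
            f"need at least k+1={k + 1} instances to form a {k}-neighbourhood, got {n}"
        )
    d = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(d, np.inf)
    # stable sort keeps the original (lower-index-first) order among ties
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    same = y[order] == y[:, None]
    return same.sum(axis=1)


def neighborhood_purity(feature_values, labels, k):
    """Neighbourhood purity U of every instance on one feature.

    U is the fraction of the instance's k nearest neighbours (on the feature
    axis, self excluded, distance ties to the lower index) that carry the
    same class label.  Values are multiples of 1/k in [0, 1].
    """
    return purity_counts(feature_values, labels, k) / k


def blur_count_threshold(k, mu):
    """Largest same-class neighbour count that still counts as blur-discerned.

    An instance is blur-discerned when its purity is <= mu, clear-discerned
    when strictly greater.  The comparison count/k <= mu is made in exact
    rational arithmetic so floating-point representation of mu can never flip
    a boundary case (with k=3 and mu=0.66, a count of 2 — purity 2/3 — is
    clear).
    """
    if not 0 < mu < 1:
        raise ValueError(f"mu must lie in (0, 1), got {mu}")
    frac = Fraction(mu)
    return (frac.numerator * k) // frac.denominator


def discern(purities, mu):
    """Blur mask from a purity vector: True where purity <= mu (blur-discerned)."""
    p = np.asarray(purities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("purities must lie in [0, 1]")
    return p <= mu


@dataclass(frozen=True)
class PurityProfile:
    """Per-instance purity of one feature together with its blur mask."""

    purities: np.ndarray
    blur_mask: np.ndarray
    k: int
    mu: float
    counts: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_feature(cls, feature_values, labels, k, mu):
        counts = purity_counts(feature_values, labels, k)
        thresh = blur_count_threshold(k, mu)
        return cls(
            purities=counts / k,
            blur_mask=counts <= thresh,
            k=k,
            mu=mu,
            counts=counts,
        )


@dataclass
class RESIParams:
    """Tunable parameters of the RESI selector.

    k is the neighbourhood size, mu the clear/blur purity threshold, epsilon
    the irrelevance cutoff on |t|, max_features the stopping bound, and
    min_merit an optional early stop when the best merit falls below it
    (disabled by default).
    """

    k: int = 3
    mu: float = 0.66
    epsilon: float = 0.1
    max_features: int = 80
    min_merit: float | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0 < self.mu < 1:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.max_features < 1:
            raise ValueError(f"max_features must be >= 1, got {self.max_features}")


def remi(blur_p, blur_q):
    """Redundancy of feature q to feature p measured on instances (REMI).

    REMI(p; q) is the fraction of p's blur-discerned instances that are also
    blur-discerned on q.  It is 0 when q clear-discerns everything p blurs
    (fully complementary predictive power) and 1 when q adds nothing.  When p
    has no blur instance the ratio is 0/0; the package defines it as 0 (a
    feature that clear-discerns every instance incurs and causes no penalty).

    Note the argument order: in the J_REMI merit the *candidate* feature is
    the first argument, i.e. the penalty is normalised by the candidate's own
    blur count.
    """
    bp = np.asarray(blur_p, dtype=bool)
    bq = np.asarray(blur_q, dtype=bool)
    if bp.shape != bq.shape:
        raise ValueError(f"blur masks differ in length: {bp.shape} vs {bq.shape}")
    denom = int(bp.sum())
    if denom == 0:
        return 0.0
    return int((bp & bq).sum()) / denom


def t_statistic(feature_values, labels):
    """Unequal-variance two-sample t-statistic of one feature.

    (mean_1 - mean_2) / sqrt(var_1/n_1 + var_2/n_2) with sample (n-1)
    variances; class 1 is the first label in sorted order, so only the
    magnitude is convention-free.  A zero denominator yields 0 when the class
    means are equal and signed infinity (maximal relevance) otherwise.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    a = x[y == classes[0]]
    b = x[y == classes[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least 2 instances")
    diff = a.mean() - b.mean()
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def t_statistics(X, y01):
    """Vectorised t-statistic (positive-class mean minus negative) per feature.

    Parameters
    ----------
    X : ndarray of shape (n, m)
    y01 : ndarray of shape (n,) with values in {0, 1}; 1 is the positive class.

    Returns
    -------
    ndarray of shape (m,), signed; zero-variance features with equal means
    give 0, with unequal means give signed inf.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01)
    pos = X[y01 == 1]
    neg = X[y01 == 0]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs at least 2 instances")
    diff = pos.mean(axis=0) - neg.mean(axis=0)
    denom = np.sqrt(
        pos.var(axis=0, ddof=1) / pos.shape[0] + neg.var(axis=0, ddof=1) / neg.shape[0]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0.0) & (diff == 0.0)] = 0.0
    t[(denom == 0.0) & (diff != 0.0)] = np.sign(diff[(denom == 0.0) & (diff != 0.0)]) * np.inf
    return t


def j_remi(candidate_abs_t, remi_to_selected):
    """Merit of a candidate: |t| minus the mean REMI of the candidate to the
    selected features.  The selected set must be non-empty (the first feature
    is seeded by |t| alone)."""
    r = np.asarray(remi_to_selected, dtype=float)
    if r.size == 0:
        raise ValueError("selected set is empty; the first feature is chosen by |t| alone")
    return float(candidate_abs_t - r.mean())
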
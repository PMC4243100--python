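"""Repeated stratified cross-validation benchmark with balanced accuracy.

The protocol: stratified 10-fold CV repeated 10 times; inside every fold the
expression matrix is standardized to zero mean / unit (sample) SD on the
training split and the test split is transformed with the training moments;
every selector sees the training split only; its ranking is truncated at each
requested dimension; each classifier is trained on the selected training
columns and scored on the test split with balanced accuracy, the mean of
sensitivity and specificity — the honest score under class imbalance.

Method comparisons use a paired two-sided t-test per (dataset, classifier)
cell; a comparison is a win for the first method only when the difference is
significant at the requested level and in its favour, otherwise a tie.
The pairing unit defaults to the repetition means (10 pairs), which avoids
the within-repetition dependence of fold-level pairing; fold pairing remains
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import ContingencyCounts

__all__ = [
    "stratified_folds",
    "standardize_fold",
    "bacc",
    "default_classifiers",
    "benchmark",
    "wtl",
    "wtl_summary",
    "WTLSummary",
]


def stratified_folds(labels, n_folds, seed):
    """Disjoint stratified test-fold index sets covering all instances.

    Per-class counts across folds differ by at most one; deterministic for a
    given seed.  A class smaller than ``n_folds`` is rejected by name.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise ValueError(
                f"class {cls!r} has {cnt} instance(s), fewer than n_folds={n_folds}"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    return [test for _, test in skf.split(np.zeros((y.shape[0], 1)), y)]


def standardize_fold(train, test):
    """Zero-mean / unit-sample-SD transform fit on train, applied to both.

    A training feature with zero SD maps to all-zeros in train and test (it
    carries no information and must not produce infinities).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training instances to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    sd_safe = np.where(degenerate, 1.0, sd)
    train_s = (train - mean) / sd_safe
    test_s = (test - mean) / sd_safe
    train_s[:, degenerate] = 0.0
    test_s[:, degenerate] = 0.0
    return train_s, test_s


def bacc(c: ContingencyCounts) -> float:
    """Balanced accuracy: (sensitivity + specificity) / 2."""
    if c.tp + c.fn < 1 or c.tn + c.fp < 1:
        raise ValueError("balanced accuracy is undefined when a class is absent")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def default_classifiers():
    """The six benchmark classifier configurations.

    Linear SVM with C=1, a degree-2 polynomial-kernel SVM, 3-NN, logistic
    regression, Gaussian naive Bayes and an entropy-split decision tree.
    Factories take a seed so any internal randomness is reproducible.
    """
    return {
        "svm": lambda seed: SVC(kernel="linear", C=1.0, random_state=seed),
        "smo": lambda seed: SVC(kernel="poly", degree=2, C=1.0, random_state=seed),
        "knn": lambda seed: KNeighborsClassifier(n_neighbors=3),
        "lr": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
        "nb": lambda seed: GaussianNB(),
        "j48": lambda seed: DecisionTreeClassifier(criterion="entropy", random_state=seed),
    }


def benchmark(ds, selectors, dimensions, classifiers=None, n_reps=10, n_folds=10, seed=0,
              return_selections=False):
    """Run the full protocol and return a tidy score table.

    Parameters
    ----------
    ds : ExpressionDataset
    selectors : mapping name -> fitted-able selector estimator (cloned per
        fold; ``max_features`` is raised to max(dimensions) when supported).
    dimensions : iterable of int — ranking prefix sizes to score.
    classifiers : mapping name -> factory(seed) -> sklearn classifier;
        defaults to :func:`default_classifiers`.
    n_reps, n_folds : repetition and fold counts (10 x 10 by default).
    seed : int master seed for fold shuffling and classifier randomness.

    Returns
    -------
    DataFrame with columns selector, dimension, classifier, rep, fold, bacc,
    truncated.  All cells of a repetition share the same fold partition.  A
    selector returning fewer features than a requested dimension is scored on
    the available prefix with ``truncated=True``.

    With ``return_selections=True`` a second value maps (selector, rep, fold)
    to the tuple of selected feature indices, so callers can verify that
    selection depends on training folds only.
    """
    classifiers = classifiers or default_classifiers()
    dimensions = sorted(int(d) for d in dimensions)
    max_dim = dimensions[-1]
    y01 = ds.y01
    master = np.random.SeedSequence(int(seed))
    rep_seeds = master.generate_state(2 * n_reps) % (2**31 - 1)
    records = []
    selections = {}
    for rep in range(n_reps):
        folds = stratified_folds(y01, n_folds, int(rep_seeds[2 * rep]))
        clf_seed = int(rep_seeds[2 * rep + 1])
        for fold_idx, test_idx in enumerate(folds):
            train_mask = np.ones(ds.n_instances, dtype=bool)
            train_mask[test_idx] = False
            X_tr, X_te = standardize_fold(
                ds.values[train_mask], ds.values[test_idx]
            )
            y_tr, y_te = y01[train_mask], y01[test_idx]
            if y_te.sum() == 0 or y_te.sum() == y_te.size:
                warnings.warn(
                    f"rep {rep} fold {fold_idx}: test fold lacks a class; skipped"
                )
                continue
            for sel_name, proto in selectors.items():
                sel = clone(proto)
                if "max_features" in sel.get_params():
                    sel.set_params(max_features=max_dim)
                sel.fit(X_tr, y_tr)
                ranking = np.asarray(sel.ranking_)
                selections[(sel_name, rep, fold_idx)] = tuple(int(i) for i in ranking)
                for dim in dimensions:
                    cols = ranking[:dim]
                    truncated = cols.size < dim
                    for clf_name, factory in classifiers.items():
                        clf = factory(clf_seed)
                        clf.fit(X_tr[:, cols], y_tr)
                        pred = np.asarray(clf.predict(X_te[:, cols]))
                        score = bacc(ContingencyCounts.from_predictions(y_te, pred))
                        records.append(
                            (sel_name, dim, clf_name, rep, fold_idx, score, truncated)
                        )
    table = pd.DataFrame.from_records(
        records,
        columns=["selector", "dimension", "classifier", "rep", "fold", "bacc", "truncated"],
    )
    if return_selections:
        return table, selections
    return table


def wtl(scores_a, scores_b, alpha=0.05):
    """Paired two-sided t-test verdict: 'win' (a better), 'tie' or 'loss'.

    Degenerate all-equal pairs are a tie by definition.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    diff = a - b
    if np.allclose(diff, 0.0):
        return "tie"
    if np.allclose(diff, diff[0]):
        # constant non-zero difference: zero variance, infinitely significant
        return "win" if diff[0] > 0 else "loss"
    _, p = ttest_rel(a, b)
    if np.isnan(p) or p >= alpha:
        return "tie"
    return "win" if diff.mean() > 0 else "loss"


@dataclass
class WTLSummary:
    """Wins/ties/losses of method A over method B aggregated across cells."""

    method_a: str
    method_b: str
    wins: int = 0
    ties: int = 0
    losses: int = 0
    alpha: float = 0.05
    cells: list = field(default_factory=list)

    @property
    def n_comparisons(self):
        return self.wins + self.ties + self.losses

    def __str__(self):
        return (
            f"{self.method_a} vs {self.method_b}: "
            f"{self.wins}-{self.ties}-{self.losses} (alpha={self.alpha})"
        )


def _paired_vectors(table, method, classifier, dimension, pairing):
    sub = table[(table.selector == method) & (table.classifier == classifier)]
    if dimension is not None:
        sub = sub[sub.dimension == dimension]
    if pairing == "reps":
        return sub.groupby("rep")["bacc"].mean().sort_index()
    if pairing == "folds":
        return sub.groupby(["rep", "fold"])["bacc"].mean().sort_index()
    raise ValueError(f"pairing must be 'reps' or 'folds', got {pairing!r}")


def wtl_summary(tables, method_a, method_b, alpha=0.05, pairing="reps", dimension=None):
    """Aggregate paired-t-test verdicts over (dataset, classifier) cells.

    Parameters
    ----------
    tables : mapping dataset name -> score table from :func:`benchmark`
        (a bare DataFrame is treated as a single unnamed dataset).
    method_a, method_b : selector names to compare (verdicts favour A).
    alpha : significance level.
    pairing : "reps" (default) pairs the repetition means; "folds" pairs the
        individual fold scores.
    dimension : int or None — score at one dimension, or None to average the
        whole sweep within each pairing unit.
    """
    if isinstance(tables, pd.DataFrame):
        tables = {"dataset": tables}
    summary = WTLSummary(method_a=method_a, method_b=method_b, alpha=alpha)
    for ds_name, table in tables.items():
        for clf in sorted(table.classifier.unique()):
            va = _paired_vectors(table, method_a, clf, dimension, pairing)
            vb = _paired_vectors(table, method_b, clf, dimension, pairing)
            joined = pd.concat([va, vb], axis=1, keys=["a", "b"]).dropna()
            verdict = wtl(joined["a"].to_numpy(), joined["b"].to_numpy(), alpha)
            summary.cells.append((ds_name, clf, verdict))
            if verdict == "win":
                summary.wins += 1
            elif verdict == "loss":
                summary.losses += 1
            else:
                summary.ties += 1
    return summary
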
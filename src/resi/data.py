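"""Dataset container and delimited-text I/O.

Expression matrices ship both as instances-in-rows and features-in-rows
files; the orientation is always an explicit argument, never guessed, because
silent transposition is the classic microarray bug.  Missing cells (empty or
"NA") are imputed with the feature's mean over the non-missing entries at
load time, so a constructed :class:`ExpressionDataset` never carries NaNs.

Labels are mapped internally so that the *smaller* class is the positive one,
which keeps sensitivity pointed at the minority class on imbalanced cohorts;
the mapping is recorded on the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DatasetValidationError, ParseError, UnsupportedTaskError

__all__ = [
    "ExpressionDataset",
    "ContingencyCounts",
    "load_dataset",
    "write_dataset",
    "validate",
]


@dataclass
class ExpressionDataset:
    """A numeric expression matrix (n instances x m features) with binary labels.

    Attributes
    ----------
    values : ndarray of shape (n, m)
    labels : ndarray of shape (n,) — the original label values.
    feature_ids, instance_ids : lists of unique identifiers.
    positive_label : the label of the smaller class (ties broken by sorted
        order); ``y01`` is 1 for positive instances.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list
    instance_ids: list
    positive_label: object = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_ids = list(self.feature_ids)
        self.instance_ids = list(self.instance_ids)
        if self.positive_label is None:
            classes, counts = np.unique(self.labels, return_counts=True)
            if classes.size == 2:
                self.positive_label = classes[np.argmin(counts)]

    @property
    def n_instances(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]

    @property
    def y01(self):
        """0/1 label vector; 1 marks the positive (minority) class."""
        return (self.labels == self.positive_label).astype(int)

    def require_valid(self):
        violations = validate(self)
        if violations:
            raise DatasetValidationError(violations)
        return self


@dataclass(frozen=True)
class ContingencyCounts:
    """Binary confusion counts: tp/tn/fp/fn of a test fold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_predictions(cls, y_true01, y_pred01):
        t = np.asarray(y_true01).astype(bool)
        p = np.asarray(y_pred01).astype(bool)
        if t.shape != p.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


def validate(ds):
    """Return a list of invariant-violation messages (empty iff valid)."""
    violations = []
    n, m = ds.values.shape
    if len(ds.instance_ids) != n:
        violations.append(
            f"instance_ids length {len(ds.instance_ids)} != {n} matrix rows"
        )
    if len(ds.feature_ids) != m:
        violations.append(
            f"feature_ids length {len(ds.feature_ids)} != {m} matrix columns"
        )
    if ds.labels.shape[0] != n:
        violations.append(f"labels length {ds.labels.shape[0]} != {n} matrix rows")
    for name, ids in (("feature_ids", ds.feature_ids), ("instance_ids", ds.instance_ids)):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        if dupes:
            violations.append(f"duplicate {name}: {sorted(set(map(str, dupes)))}")
    classes, counts = np.unique(ds.labels, return_counts=True)
    if classes.size != 2:
        violations.append(f"expected exactly 2 label values, found {classes.size}")
    else:
        for cls_, cnt in zip(classes, counts):
            if cnt < 2:
                violations.append(f"class {cls_!r} has only {cnt} instance(s); need >= 2")
    if np.isnan(ds.values).any():
        violations.append("matrix contains missing values after construction")
    return violations


def _read_frame(path):
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        # round_trip parsing keeps load(write(ds)) bit-identical
        return pd.read_csv(
            path, sep=sep, index_col=0, na_values=["NA"], float_precision="round_trip"
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc


def _coerce_numeric(df, axis_name):
    """Coerce to float, naming the offending cell on failure.

    Conversion goes through Python's ``float`` (correctly rounded), so a
    value written with full precision reads back bit-identically even when
    the column arrived as strings (features-in-rows files mix the label row
    into every column, defeating read_csv's numeric parsing).
    """
    def convert(value, row, col):
        if pd.isna(value):
            return np.nan
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric value {value!r} at {axis_name} {row!r}, column {col!r}"
            ) from None

    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        out[col] = [convert(v, row, col) for row, v in df[col].items()]
    return out


def load_dataset(path, orientation="instances", label="class"):
    """Load a delimited expression matrix with a binary label.

    Parameters
    ----------
    path : str or Path
        CSV (or TSV for ``.tsv``/``.txt``) file with one header line and an
        identifier first column.
    orientation : {"instances", "features"}
        "instances": rows are instances and ``label`` names the label column.
        "features": rows are features and ``label`` names the label row.
    label : str
        Identifier of the label column/row.

    Missing numeric cells (empty or "NA") are imputed with the feature mean
    over the non-missing entries; a feature with no observed value at all is
    rejected by id.
    """
    if orientation not in ("instances", "features"):
        raise ValueError(f"orientation must be 'instances' or 'features', got {orientation!r}")
    df = _read_frame(path)
    if orientation == "features":
        if label not in df.index:
            raise ParseError(f"label row {label!r} not found in {path}")
        labels = df.loc[label]
        df = df.drop(index=label).T  # now instances in rows
        labels = labels.loc[df.index]
    else:
        if label not in df.columns:
            raise ParseError(f"label column {label!r} not found in {path}")
        labels = df[label]
        df = df.drop(columns=label)

    classes = pd.unique(labels.dropna())
    if len(classes) != 2:
        raise UnsupportedTaskError(
            f"{path}: expected a binary label, found {len(classes)} level(s): "
            f"{sorted(map(str, classes))}"
        )

    values = _coerce_numeric(df, "instance")
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise DatasetValidationError(
            [f"feature {f!r} has no observed values to impute from" for f in all_missing]
        )
    values = values.fillna(values.mean(axis=0))

    ds = ExpressionDataset(
        values=values.to_numpy(dtype=float),
        labels=labels.to_numpy(),
        feature_ids=[str(c) for c in values.columns],
        instance_ids=[str(i) for i in values.index],
    )
    return ds.require_valid()


def write_dataset(ds, path, orientation="instances", label="class"):
    """Write a dataset back to delimited text (inverse of :func:`load_dataset`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(ds.values, index=ds.instance_ids, columns=ds.feature_ids)
    df.insert(0, label, ds.labels)
    if orientation == "features":
        df = df.T
    df.to_csv(path, sep=sep)
    return path
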
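"""Planted-structure generator for microarray-like binary datasets.

The generator emulates the few-samples / many-features regime of tumour
expression cohorts (tens of instances, hundreds to thousands of features,
imbalanced binary labels) with four planted feature roles:

* relevant    — class-conditional Gaussians shifted by ±effect_size/2;
* duplicate   — copies of a relevant source, plus optional Gaussian noise;
* complementary — pairs (f, g) where f separates the classes cleanly on one
  designated half of the instances and is pure noise on the other half, and
  g mirrors it, so each member's blur-discerned instances are exactly the
  half the other member handles;
* irrelevant  — label-independent standard normal noise.

Relevant and complementary features are empirically standardized within each
class before the class shift is applied, so every planted informative
feature carries exactly the same sample effect size (and hence an identical
|t|).  Planted relevance is thereby deterministic and the order in which a
selector picks the informative features is governed purely by their
redundancy structure — which is the property the generator exists to probe.
Irrelevant features are left raw so their |t| follows the null distribution.

Ground-truth roles are returned alongside the data so tests can assert on
roles rather than column positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "generate"]

ROLE_RELEVANT = "relevant"
ROLE_DUPLICATE = "duplicate"
ROLE_COMPLEMENTARY = "complementary"
ROLE_IRRELEVANT = "irrelevant"
INFORMATIVE_ROLES = (ROLE_RELEVANT, ROLE_COMPLEMENTARY)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults describe the reference condition used throughout the test
    suite: 60 instances with a 20/40 class split (the imbalance of a typical
    small tumour cohort), two relevant features at effect size 2 SD, one
    exact duplicate of the first relevant feature, one complementary pair
    and 200 irrelevant features.

    duplicate_blocks entries are (source relevant index, copies, noise SD).
    Complementary separation is 3 x effect_size with a cluster SD of
    separation/40 and off-half noise SD of separation/12 — wide enough that
    the clean half is clear-discerned with near certainty, while the overall
    |t| matches the relevant features.
    """

    n: int = 60
    class_ratio: float = 1 / 3
    n_relevant: int = 2
    effect_size: float = 2.0
    duplicate_blocks: tuple = ((0, 1, 0.0),)
    n_complementary_pairs: int = 1
    n_irrelevant: int = 200
    seed: int = 0

    @property
    def n_positive(self):
        return int(round(self.n * self.class_ratio))

    @property
    def n_features(self):
        copies = sum(c for _, c, _ in self.duplicate_blocks)
        return self.n_relevant + copies + 2 * self.n_complementary_pairs + self.n_irrelevant

    def validate(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        n_pos = self.n_positive
        if n_pos < 2 or self.n - n_pos < 2:
            raise ValueError(
                f"each class needs >= 2 instances (got {n_pos}/{self.n - n_pos})"
            )
        for src, copies, sd in self.duplicate_blocks:
            if not 0 <= src < self.n_relevant:
                raise ValueError(f"duplicate source {src} is not a relevant feature index")
            if copies < 1 or sd < 0:
                raise ValueError("duplicate blocks need copies >= 1 and noise SD >= 0")
        return self


def _class_standardize(x, y01):
    """Zero mean, unit sample SD within each class (in place on a copy)."""
    out = np.array(x, dtype=float)
    for cls in (0, 1):
        idx = y01 == cls
        sd = out[idx].std(ddof=1)
        out[idx] = (out[idx] - out[idx].mean()) / (sd if sd > 0 else 1.0)
    return out


def _halves(y01):
    """Split instances into two halves, stratified within class by parity."""
    half_a = np.zeros(y01.shape[0], dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        half_a[idx[::2]] = True
    return half_a


def generate(spec: SyntheticSpec):
    """Generate (dataset, ground_truth) deterministically from ``spec.seed``.

    ground_truth maps feature id -> role string; duplicates additionally
    appear as ``dup<i>_of_<source id>`` so their provenance is explicit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, n_pos = spec.n, spec.n_positive
    y01 = np.zeros(n, dtype=int)
    y01[:n_pos] = 1
    shift = np.where(y01 == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)

    columns, feature_ids, roles = [], [], {}

    relevant_cols = []
    for j in range(spec.n_relevant):
        col = _class_standardize(rng.standard_normal(n), y01) + shift
        relevant_cols.append(col)
        columns.append(col)
        fid = f"rel{j}"
        feature_ids.append(fid)
        roles[fid] = ROLE_RELEVANT

    for src, copies, noise_sd in spec.duplicate_blocks:
        for c in range(copies):
            col = relevant_cols[src].copy()
            if noise_sd > 0:
                col = col + rng.normal(0.0, noise_sd, n)
            columns.append(col)
            fid = f"dup{c}_of_rel{src}"
            feature_ids.append(fid)
            roles[fid] = ROLE_DUPLICATE

    half_a = _halves(y01)
    sep = 3.0 * spec.effect_size
    cluster_sd = sep / 40.0
    noise_sd = sep / 12.0
    for p in range(spec.n_complementary_pairs):
        for tag, clean_half in (("a", half_a), ("b", ~half_a)):
            col = np.empty(n)
            centers = np.where(y01 == 1, sep / 2.0, -sep / 2.0)
            col[clean_half] = centers[clean_half] + rng.normal(
                0.0, cluster_sd, int(clean_half.sum())
            )
            col[~clean_half] = rng.normal(0.0, noise_sd, int((~clean_half).sum()))
            col = _class_standardize(col, y01) + shift
            columns.append(col)
            fid = f"comp{p}{tag}"
            feature_ids.append(fid)
            roles[fid] = ROLE_COMPLEMENTARY

    for j in range(spec.n_irrelevant):
        columns.append(rng.standard_normal(n))
        fid = f"irr{j}"
        feature_ids.append(fid)
        roles[fid] = ROLE_IRRELEVANT

    values = np.column_stack(columns) if columns else np.empty((n, 0))
    labels = np.where(y01 == 1, "case", "control")
    ds = ExpressionDataset(
        values=values,
        labels=labels,
        feature_ids=feature_ids,
        instance_ids=[f"s{i:03d}" for i in range(n)],
        positive_label="case",
    )
    return ds, roles
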
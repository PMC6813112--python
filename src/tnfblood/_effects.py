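"""Vectorized contrast-effect estimators used inside permutation tests.

Permutation nulls for concordance and set-level statistics need the contrast
effect vector recomputed hundreds of times.  For the two designs used here
the weighted least-squares coefficient has a closed form that vectorizes
over features:

* paired MO3-BL with subject fixed effects: the coefficient equals the
  precision-weighted mean of per-subject (MO3 - BL) log-expression
  differences, each difference weighted by the collapsed observation
  weights ``1 / (1/w_BL + 1/w_MO3)``;
* two-group GR-NR: the coefficient equals the difference of the weighted
  group means.

The permutation null flips the sign of each subject's difference (paired)
or permutes the group labels (two-group), both vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DesignSpec, build_design, filter_low_counts, log_cpm, voom_weights


@dataclass
class PreparedContrast:
    """Feature matrix reduced to the sufficient statistics of one contrast."""

    kind: str  # "paired" | "group"
    features: pd.Index
    values: np.ndarray  # paired: G x S diffs; group: G x N log-expression
    weights: np.ndarray  # same shape
    labels: np.ndarray | None  # group: boolean GR indicator per sample
    units: list[str]  # subjects (paired) or samples (group)

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def effects(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Effect vector; ``perm`` is a sign vector (paired) or permuted labels."""
        if self.kind == "paired":
            signs = np.ones(self.n_units) if perm is None else perm
            num = (self.weights * self.values * signs).sum(axis=1)
            den = self.weights.sum(axis=1)
            return num / den
        labels = self.labels if perm is None else perm
        w1 = self.weights[:, labels]
        w0 = self.weights[:, ~labels]
        m1 = (w1 * self.values[:, labels]).sum(axis=1) / w1.sum(axis=1)
        m0 = (w0 * self.values[:, ~labels]).sum(axis=1) / w0.sum(axis=1)
        return m1 - m0

    def null_draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "paired":
            return rng.choice([-1.0, 1.0], size=self.n_units)
        return rng.permutation(self.labels)


def prepare_contrast(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec,
    is_counts: bool = True,
) -> PreparedContrast:
    """Reduce a dataset to the sufficient statistics of one contrast."""
    meta = meta.loc[matrix.columns]
    if spec.contrast == "GR-NR" and spec.visit_col in meta:
        meta = meta.loc[meta[spec.visit_col] == "BL"]
        matrix = matrix[meta.index]

    if is_counts:
        matrix = filter_low_counts(matrix)
        lib = matrix.sum(axis=0).to_numpy()
        X, _, _ = build_design(meta, spec)
        y = log_cpm(matrix)
        w = voom_weights(y, X, lib_size=lib).to_numpy()
        yv = y.to_numpy()
    else:
        yv = matrix.to_numpy(dtype=float)
        w = np.ones_like(yv)

    if spec.contrast == "MO3-BL":
        subjects = list(pd.unique(meta[spec.subject_col]))
        diffs, wts = [], []
        for s in subjects:
            rows = meta.index[meta[spec.subject_col] == s]
            bl = [r for r in rows if meta.loc[r, spec.visit_col] == "BL"]
            mo3 = [r for r in rows if meta.loc[r, spec.visit_col] == "MO3"]
            if len(bl) != 1 or len(mo3) != 1:
                continue
            ib = matrix.columns.get_loc(bl[0])
            im = matrix.columns.get_loc(mo3[0])
            diffs.append(yv[:, im] - yv[:, ib])
            wts.append(1.0 / (1.0 / w[:, im] + 1.0 / w[:, ib]))
        if len(diffs) < 3:
            raise ValueError("need >= 3 complete BL/MO3 pairs")
        return PreparedContrast(
            kind="paired",
            features=matrix.index,
            values=np.column_stack(diffs),
            weights=np.column_stack(wts),
            labels=None,
            units=[s for s in subjects],
        )

    if spec.contrast == "GR-NR":
        labels = meta[spec.response_col].astype(str).isin(["good", "GR"]).to_numpy()
        if min(labels.sum(), (~labels).sum()) < 2:
            raise ValueError("contrast needs >= 2 samples per level")
        return PreparedContrast(
            kind="group",
            features=matrix.index,
            values=yv,
            weights=w,
            labels=labels,
            units=list(matrix.columns),
        )

    raise ValueError(f"unknown contrast {spec.contrast!r}")


def dataset_rng(seed: int, prepared: PreparedContrast) -> np.random.Generator:
    """RNG keyed by the master seed and a dataset fingerprint.

    The fingerprint depends only on the dataset's own sample units, so the
    permutation stream a dataset receives is invariant to the order in which
    datasets are passed to a two-dataset test.
    """
    import zlib

    fp = zlib.crc32("|".join(map(str, prepared.units)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), fp]))
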
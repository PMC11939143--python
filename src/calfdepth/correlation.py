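"""Correlation structure of body metrics and body weight across age.

Pearson correlation matrices over the per-calf-date medians, age-quartile
stratification, and Mantel permutation tests comparing the correlation
structure between age groups: a small Mantel p indicates that the
metric-weight correlation structure is preserved as calves grow, which is
what licenses forecasting later weight from early measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth_io import ValidationError

__all__ = ["CorrelationMatrix", "pearson_matrix", "quartile_groups", "mantel"]

DEFAULT_COLUMNS = [
    "width_px",
    "length_px",
    "avg_height_mm",
    "volume_mm_px2",
    "contour_area_px2",
    "bw_lb",
]


@dataclass
class CorrelationMatrix:
    """A labelled symmetric Pearson correlation matrix with its sample size."""

    labels: list[str]
    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("correlation matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def pearson_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over complete rows.

    A zero-variance column yields NaN correlations (flagged as undefined,
    never silently 0).
    """
    columns = columns or [c for c in DEFAULT_COLUMNS if c in table.columns]
    if len(columns) < 2:
        raise ValidationError("need at least 2 numeric columns")
    sub = table[columns].dropna()
    if len(sub) < 3:
        raise ValidationError("need at least 3 complete rows")
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(labels=list(columns), values=corr, n=len(sub))


def quartile_groups(
    table: pd.DataFrame, by: str = "age_days"
) -> list[tuple[str, pd.DataFrame]]:
    """Split rows into four groups at the 25/50/75th percentiles of ``by``.

    Quartile edges use the nearest-rank convention, with rows tied at an
    edge going to the lower group. Group labels report the realized
    value range, e.g. ``"21-30"``.
    """
    if by not in table.columns:
        raise ValidationError(f"column {by!r} not in table")
    values = pd.to_numeric(table[by])
    if len(table) < 8:
        raise ValidationError("need at least 8 rows to form quartiles")
    if values.nunique() < 4:
        raise ValidationError("degenerate quartiles: too few distinct values")
    edges = np.percentile(values, [25, 50, 75], method="inverted_cdf")
    masks = [
        values <= edges[0],
        (values > edges[0]) & (values <= edges[1]),
        (values > edges[1]) & (values <= edges[2]),
        values > edges[2],
    ]
    out = []
    for sel_mask in masks:
        sel = table[sel_mask]
        if sel.empty:
            raise ValidationError("degenerate quartiles: empty group")
        vr = pd.to_numeric(sel[by])
        out.append((f"{vr.min():g}-{vr.max():g}", sel))
    return out


def mantel(
    m1: CorrelationMatrix,
    m2: CorrelationMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test between two correlation matrices.

    The statistic is the Pearson correlation of the off-diagonal upper
    triangles. Significance is one-sided (positive association): rows and
    columns of the second matrix are permuted simultaneously and
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``, so with 999
    permutations the smallest attainable p is 0.001.
    """
    if m1.labels != m2.labels:
        raise ValidationError("matrices must share labels and order")
    if n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    k = len(m1.labels)
    iu = np.triu_indices(k, k=1)

    def upper(mat: np.ndarray) -> np.ndarray:
        return mat[iu]

    a = upper(m1.values)
    rng = np.random.default_rng(seed)
    r_obs = float(np.corrcoef(a, upper(m2.values))[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        shuffled = m2.values[np.ix_(perm, perm)]
        r_perm = float(np.corrcoef(a, upper(shuffled))[0, 1])
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p
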
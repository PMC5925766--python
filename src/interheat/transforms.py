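"""Pre-scaling transforms applied before clustering and color-mapping.

Heatmap color scales are shared across the whole matrix, so columns on
incommensurable scales must first be brought to a comparable one:

``sqrt``
    Square root of every cell — compresses the right tail of count data so
    a few extreme observations do not absorb the entire color range.
``scale``
    Per-column z-score (mean 0, sample sd 1); appropriate for roughly
    normal columns.
``normalize``
    Per-column min-max map onto [0, 1]; preserves each column's
    distributional shape.
``percentize``
    Per-column empirical CDF evaluated at each value — the fraction of
    observations at or below it; a rank-like transform with a direct
    probability reading.
``is_na10``
    0/1 missingness indicator, for exploring the sparseness of a dataset.

Missing values propagate (NaN in, NaN out) and are excluded from every
statistic (mean, sd, min, max, ECDF denominator). Constant columns map to
all zeros under scale/normalize rather than raising, so pipelines on
degenerate data do not abort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import DataMatrix

__all__ = [
    "TransformSpec",
    "TransformError",
    "apply_transform",
    "sqrt_transform",
    "scale_columns",
    "normalize_columns",
    "percentize_columns",
    "is_na10",
]

KINDS = ("none", "sqrt", "scale", "normalize", "percentize", "is_na10")


class TransformError(ValueError):
    pass


@dataclass(frozen=True)
class TransformSpec:
    """Which transform to apply and over which margin.

    ``axis="column"`` (the default) treats each column as a variable;
    ``axis="row"`` transposes that; ``axis="global"`` only matters for the
    cell-wise transforms (sqrt, is_na10), which ignore the margin anyway.
    """

    kind: str = "none"
    axis: str = "column"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TransformError(f"unknown transform {self.kind!r}; choose from {KINDS}")
        if self.axis not in ("column", "row", "global"):
            raise TransformError(f"unknown axis {self.axis!r}")


def _per_column(m: DataMatrix, axis: str, fn) -> DataMatrix:
    if axis == "row":
        return _per_column(m.transpose(), "column", fn).transpose()
    out = m.values.astype(float).copy()
    for j in range(out.shape[1]):
        out[:, j] = fn(out[:, j], j)
    return m.copy_with(out)


def sqrt_transform(m: DataMatrix) -> DataMatrix:
    """Cell-wise square root; requires all non-missing values >= 0."""
    v = m.values
    bad = np.argwhere((v < 0) & ~np.isnan(v))
    if bad.size:
        i, j = bad[0]
        raise TransformError(
            f"sqrt transform needs non-negative values; cell "
            f"({m.row_labels[i]!r}, {m.col_labels[j]!r}) = {v[i, j]}")
    return m.copy_with(np.sqrt(v))


def scale_columns(m: DataMatrix, axis: str = "column") -> DataMatrix:
    """Z-score each column: mean 0, sample (n-1) sd 1. Constant columns -> 0."""
    def f(col, j):
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            lab = m.col_labels[j] if axis == "column" else m.row_labels[j]
            raise TransformError(
                f"scale needs >=2 non-missing values; margin {lab!r} has {obs.size}")
        sd = obs.std(ddof=1)
        if sd == 0:
            return np.where(np.isnan(col), np.nan, 0.0)
        return (col - obs.mean()) / sd
    return _per_column(m, axis, f)


def normalize_columns(m: DataMatrix, axis: str = "column") -> DataMatrix:
    """Affinely map each column onto [0, 1] (min -> 0, max -> 1).

    Shape-preserving within a column. Constant columns map to all zeros.
    """
    def f(col, j):
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            lab = m.col_labels[j] if axis == "column" else m.row_labels[j]
            raise TransformError(f"normalize: margin {lab!r} is entirely missing")
        lo, hi = obs.min(), obs.max()
        if hi == lo:
            return np.where(np.isnan(col), np.nan, 0.0)
        return (col - lo) / (hi - lo)
    return _per_column(m, axis, f)


def percentize_columns(m: DataMatrix, axis: str = "column") -> DataMatrix:
    """Replace each value by its column's empirical CDF at that value.

    Cell (i, j) becomes the fraction of non-missing values in column j that
    are <= values[i, j]; ties share an output, outputs lie in (0, 1].
    """
    def f(col, j):
        obs_mask = ~np.isnan(col)
        obs = col[obs_mask]
        if obs.size == 0:
            lab = m.col_labels[j] if axis == "column" else m.row_labels[j]
            raise TransformError(f"percentize: margin {lab!r} is entirely missing")
        out = np.full_like(col, np.nan)
        # ECDF at own values: count of obs <= v, via searchsorted on sorted obs
        srt = np.sort(obs)
        out[obs_mask] = np.searchsorted(srt, obs, side="right") / obs.size
        return out
    return _per_column(m, axis, f)


def is_na10(m: DataMatrix) -> DataMatrix:
    """0/1 missingness indicator; the output has no missing cells."""
    return m.copy_with(np.isnan(m.values).astype(float))


def apply_transform(m: DataMatrix, spec: TransformSpec) -> DataMatrix:
    if spec.kind == "none":
        return m
    if spec.kind == "sqrt":
        return sqrt_transform(m)
    if spec.kind == "is_na10":
        return is_na10(m)
    axis = "column" if spec.axis == "global" else spec.axis
    fn = {"scale": scale_columns, "normalize": normalize_columns,
          "percentize": percentize_columns}[spec.kind]
    return fn(m, axis=axis)
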
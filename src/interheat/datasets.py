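"""Deterministic synthetic matrices for demonstrations and tests.

Three generators cover the pipeline's feature surface without any external
data:

* :func:`planted_clusters` — Gaussian blobs around well-separated centroids;
  row labels encode the true cluster, so recovery of the planted k by the
  silhouette search is directly checkable.
* :func:`surveillance_counts` — a disease-incidence-style matrix
  (regions x years) of right-tailed, overdispersed counts per 100 000
  population whose rates collapse after an intervention year, emulating the
  shape of pre-/post-vaccine measles surveillance tables. Counts are
  Gamma-Poisson (negative-binomial-like): region susceptibility ~
  Gamma(4, 1/4) and per-year epidemic intensity ~ Gamma(2, 1/2) multiply a
  base rate of 300 cases per 100 000; after the intervention the rate decays
  by a factor 0.45 per year on top of an immediate 80% drop.
* :func:`sprinkle_missing` — masks an exact fraction of cells, for
  exercising missing-value handling and the missingness-indicator view.

All generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

import numpy as np

from .matrix_io import DataMatrix

__all__ = ["planted_clusters", "surveillance_counts", "sprinkle_missing"]

# surveillance_counts constants
_BASE_RATE = 300.0          # pre-intervention mean cases per 100k
_REGION_SHAPE = 4.0         # Gamma shape of region susceptibility (mean 1)
_YEAR_SHAPE = 2.0           # Gamma shape of yearly epidemic intensity (mean 1)
_POST_DROP = 0.2            # immediate post-intervention rate multiplier
_POST_DECAY = 0.45          # additional per-year decay after intervention


def planted_clusters(n_clusters: int, rows_per_cluster: int, n_cols: int,
                     separation: float = 10.0, noise_sd: float = 1.0,
                     seed: int = 0) -> DataMatrix:
    """Rows drawn around ``n_clusters`` centroids separated by
    ``separation`` in every coordinate, with Gaussian noise ``noise_sd``.

    Row labels are ``c<cluster>_r<row>`` so the planted structure can be
    recovered from labels alone.
    """
    if min(n_clusters, rows_per_cluster, n_cols) < 1:
        raise ValueError("all sizes must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c in range(n_clusters):
        centroid = np.full(n_cols, c * separation, dtype=float)
        block = centroid + rng.normal(0.0, noise_sd, size=(rows_per_cluster, n_cols))
        rows.append(block)
        labels.extend(f"c{c}_r{r}" for r in range(rows_per_cluster))
    values = np.vstack(rows)
    return DataMatrix(values, labels, [f"v{j}" for j in range(n_cols)])


def surveillance_counts(n_regions: int = 50, n_years: int = 76,
                        intervention_year_index: int = 35,
                        seed: int = 0) -> DataMatrix:
    """Overdispersed incidence counts with a sharp post-intervention drop.

    Rows are regions, columns are consecutive years starting at year 0;
    ``intervention_year_index`` is the first year affected by the
    intervention. Values are nonnegative counts per 100 000 with a heavy
    right tail — the situation where a square-root transform keeps extreme
    epidemics from absorbing the whole color range.
    """
    if not 0 <= intervention_year_index < n_years:
        raise ValueError("intervention_year_index must lie within the year range")
    rng = np.random.default_rng(seed)
    region = rng.gamma(_REGION_SHAPE, 1.0 / _REGION_SHAPE, size=n_regions)
    year = rng.gamma(_YEAR_SHAPE, 1.0 / _YEAR_SHAPE, size=n_years)
    years_since = np.arange(n_years) - intervention_year_index
    post = np.where(years_since >= 0,
                    _POST_DROP * _POST_DECAY ** years_since, 1.0)
    rate = _BASE_RATE * region[:, None] * (year * post)[None, :]
    values = rng.poisson(rate).astype(float)
    row_labels = [f"region{r + 1:02d}" for r in range(n_regions)]
    col_labels = [f"year{y:02d}" for y in range(n_years)]
    return DataMatrix(values, row_labels, col_labels)


def sprinkle_missing(m: DataMatrix, fraction: float, seed: int = 0) -> DataMatrix:
    """Mask exactly ``round(fraction * n_cells)`` cells (as NaN)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    n_cells = m.n_rows * m.n_cols
    k = int(round(fraction * n_cells))
    values = m.values.copy()
    if k:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_cells, size=k, replace=False)
        values.ravel()[flat] = np.nan
    return m.copy_with(values)
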
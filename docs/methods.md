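# Methods

This note documents the statistical procedures, defaults and numerical
choices behind `interheat`, and what the synthetic generators do and do not
emulate.

## Pipeline

`interheat.pipeline.run` executes a fixed stage order: transform →
(per axis) distance → linkage → optional cluster-count search → optimal
leaf ordering → color mapping → layout → export. Each axis is processed
independently with its own distance matrix and dendrogram; passing
`"none"` for an axis skips its tree entirely and leaves the input order
untouched (the usual choice for time-ordered columns). Errors raised inside
a stage are re-raised as `PipelineError` with the stage name prefixed.

## Transforms

All transforms operate per column by default (a row/global switch is
provided), propagate missing values (NaN in → NaN out) and exclude them
from every statistic.

* `sqrt` — cell-wise square root; rejects negative cells by name. Intended
  for right-tailed counts where a few extreme values would otherwise absorb
  the whole color range.
* `scale` — z-score with the sample (n−1) standard deviation, the
  conventional definition in statistical software. Columns with fewer than
  two observed values are an error; constant columns map to all zeros
  rather than raising, so degenerate inputs do not abort a pipeline.
* `normalize` — the min–max map (x − min)/(max − min). This is the standard
  reading of "subtract the minimum, divide by the maximum": a literal
  division by the column maximum alone would not land on [0, 1] when the
  minimum is nonzero. Constant columns map to zeros.
* `percentize` — each value becomes its column's empirical CDF evaluated at
  itself: (# observed values ≤ x) / (# observed values). Outputs lie in
  (0, 1], ties share an output, and the transform is rank-preserving within
  a column. Implemented via `searchsorted` on the sorted observed values.
* `is_na10` — the 0/1 missingness indicator; its output carries no missing
  mask of its own.

## Distances and clustering

Metrics: Euclidean, Manhattan, maximum (Chebyshev) and Pearson
dissimilarity (1 − r, clipped at zero for numerical safety). With missing
cells, distances use pairwise-complete columns; Euclidean and Manhattan
sums are rescaled by `n_cols / n_jointly_observed` (Euclidean inside the
square root), so pairs with different overlap remain comparable. A pair of
rows with zero jointly observed columns is an error naming the pair.

Agglomeration is delegated to `scipy.cluster.hierarchy.linkage` (single,
complete, average/UPGMA, and Ward in its D2 squared-distance variant — the
conventional meaning in modern software). These four linkages produce
monotone merge heights. scipy's nearest-neighbor-chain tie-breaking is
deterministic, which is what reproducible output requires. Trees are stored
in the standard linkage-matrix encoding together with the label list and a
mutable display leaf order.

`cut_tree(t, k)` removes the k−1 highest merges and renumbers the clusters
by first appearance along the display leaf order, so cluster 0 is always
the leftmost/topmost on a plot and branch colors are stable across reruns.

## Silhouette-based cluster-count selection

For point i with own-cluster mean distance a(i) (excluding itself) and
smallest other-cluster mean distance b(i), the silhouette is
s(i) = (b − a)/max(a, b); members of singleton clusters contribute 0 (the
standard convention). `find_k` scores the cuts of the already-built tree
for k = 2..10 (clipped to n−1) and keeps the cut with the highest mean
silhouette, breaking ties toward the smallest k. Only tree cuts are
considered — the search colors the branches of one clustering rather than
re-clustering per k — so the selected partition is always displayable on
the dendrogram.

## Optimal leaf ordering

A dendrogram admits 2^(n−1) leaf orders by branch flips. The seriation
module minimizes the adjacent-leaf distance sum over exactly that set with
the O(n³) dynamic program over (subtree, leftmost leaf, rightmost leaf)
states: for an internal node with children L and R,
cost(u, v) = min over x ∈ L, y ∈ R of cost_L(u, x) + d(x, y) + cost_R(y, v),
considering both child orientations (reversal preserves cost because d is
symmetric). Backtracking returns, among cost-minimal orders, the
lexicographically smallest leaf-id sequence, which makes HTML output
byte-reproducible. Because the reconstruction re-adds the same three terms
in a possibly different floating-point order than the forward pass,
feasibility during backtracking is checked with a relative tolerance of
1e-9 rather than bit equality; ties within that tolerance are resolved by
the lexicographic rule.

During development the obvious external cross-check,
`scipy.cluster.hierarchy.optimal_leaf_ordering`, turned out to return
suboptimal orders on a majority of random test instances (its path cost
exceeds the exhaustive flip-enumeration minimum, which our DP always
attains). The test suite therefore keeps exhaustive enumeration as the
authoritative oracle (all instances with n ≤ 10) and asserts only
dominance against scipy.

## Color mapping

Palette stop tables are fixed hex constants sampled from matplotlib's
colormaps: an 11-stop viridis (sequential default), a 9-stop Moreland
cool-warm (divergent default for correlations, limits pinned to (−1, 1)),
and the ColorBrewer RdBu/BrBG/RdYlBu 11-class tables as divergent
alternates. Values are clamped to the limits and interpolated
piecewise-linearly in RGB between bracketing stops — a deliberate
simplicity trade-off; the perceptual-uniformity claim is guarded by a test
that relative luminance is strictly increasing across the sequential scale.
Automatic limits are the (min, max) of the non-missing data after
transformation; quantile clipping is out of scope. Missing cells render in
mid-grey `#808080` with tooltip value `NA`. Cluster and annotation
categories draw from a fixed 10-color qualitative table, extended by an
evenly spaced hue wheel beyond ten.

## Rendering and export

The interactive figure is inline SVG plus ~40 lines of embedded vanilla
JavaScript (tooltip div, wheel zoom about the cursor via the SVG viewBox,
drag pan, double-click reset) — no external scripts or network references,
so one HTML file is the complete artifact. Geometry is computed once and
shared by the SVG and PNG backends; cells clamp between 4 px and 36 px so
very large and very small matrices both render. Row 0 of the (already
leaf-ordered) matrix is drawn at the top; dendrogram heights grow away from
the heatmap; axis labels are omitted beyond 120 rows/columns to keep files
small. Every float in the SVG is emitted with a fixed format and there are
no timestamps or generated ids, so identical inputs yield byte-identical
files. PNG export draws the same layout with matplotlib at dpi 100; the
figure size carries a quarter-pixel nudge because matplotlib truncates the
inch→pixel conversion, which would otherwise lose the last pixel row for
some requested sizes.

Tooltips follow the template `row: {row}<br>column: {col}<br>value:
{value}` with values at 6 significant digits; the template is
user-configurable.

## Synthetic data

The generators take explicit seeds, never touch global random state, and
define the package's test conditions:

* `planted_clusters(k, rows, cols, separation=10, noise_sd=1)` — Gaussian
  blobs whose centroids sit `separation` apart in every coordinate; labels
  encode the truth. Cluster-recovery tests use separation 10 with noise sd
  0.1 — well-separated structure, since they test the selection machinery,
  not the hardness frontier.
* `surveillance_counts(n_regions=50, n_years=76, intervention_year_index=35)`
  — a regions-by-years incidence matrix per 100 000 population. Counts are
  Gamma-Poisson: region susceptibility ~ Gamma(4, 1/4), yearly epidemic
  intensity ~ Gamma(2, 1/2), base rate 300 per 100k; from the intervention
  year the rate drops immediately to 20% and decays by a further factor
  0.45 per year. The defaults mirror a 50-state, 76-year vaccination-era
  surveillance table. The generator reproduces the *shape* of such data —
  nonnegative, right-tailed, overdispersed, sharp post-intervention drop —
  but not spatial correlation between neighboring regions, multi-year
  epidemic periodicity, or reporting artifacts; passing tests demonstrate
  the pipeline's behavior on this structure, not fidelity to any real
  surveillance series.
* `sprinkle_missing(m, fraction)` — masks exactly `round(fraction·cells)`
  cells, for exercising NA propagation, pairwise-complete distances and the
  missingness view.

## Problem sizes and tolerances

Exhaustive seriation oracles run at n ≤ 10 leaves (≤ 512 flip
configurations), distance/silhouette oracles at n ≤ 30, rendering checks on
25 random pipeline configurations — sizes at which brute-force ground truth
is exact and the whole verification suite completes in seconds. Silhouette
agreement is asserted to 1e-9 (measured agreement is at machine precision);
scale moments to 1e-12; seriation feasibility tolerance 1e-9 relative as
above.

## Known limitations

* Interpolation in RGB rather than a perceptual space (CIELAB); adequate
  for the bundled palettes, whose stop tables are dense.
* The OLO dynamic program is O(n³) time and memory in the worst case;
  matrices with thousands of rows will be slow to seriate.
* No Excel/HDF5/sparse input, no correlation auto-detection (the divergent
  scale is opt-in via `data_kind="correlation"`), no GUI, and no embedding
  helpers for notebook/server frameworks — the HTML file itself is the
  shareable artifact.
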
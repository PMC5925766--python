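"""End-to-end heatmap construction: one call from matrix to files.

Stage order is fixed: transform -> (per axis) distance -> linkage ->
optional silhouette search for k -> optimal-leaf-order seriation ->
color mapping -> layout -> export. Defaults mirror standard practice:
Euclidean distance, average linkage, dendrograms on both axes, OLO
seriation, sequential viridis scale with automatic limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import (ClusterAssignment, Dendrogram, agglomerate,
                         compute_distance, cut_tree, find_k, mean_silhouette)
from .colors import ColorScale, pick_default_scale
from .matrix_io import AnnotationTrack, DataMatrix
from .render import FigureBundle, LayoutConfig, build_figure, to_html, to_png
from .seriation import apply_order, olo_reorder
from .transforms import TransformSpec, apply_transform

__all__ = ["PipelineConfig", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Everything :func:`run` needs beyond the matrix itself.

    ``row_dendrogram``/``col_dendrogram`` accept ``"auto"`` (cluster the
    axis), ``"none"`` (keep input order, no tree) or a pre-built
    :class:`Dendrogram`. ``k_row``/``k_col`` accept ``None`` (no branch
    coloring), ``"auto"`` (silhouette search over k = 2..10) or an integer.
    """

    transform: TransformSpec | str = "none"
    dist_method: str = "euclidean"
    hclust_method: str = "average"
    row_dendrogram: object = "auto"
    col_dendrogram: object = "auto"
    k_row: object = None
    k_col: object = None
    seriation_method: str = "OLO"
    scale: ColorScale | str = "auto"
    data_kind: str = "plain"
    annotations: list[AnnotationTrack] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    png_size: tuple[int, int] = (900, 700)

    def __post_init__(self) -> None:
        if isinstance(self.transform, str):
            self.transform = TransformSpec(kind=self.transform)
        if self.seriation_method not in ("OLO", "identity"):
            raise ValueError("seriation_method must be 'OLO' or 'identity'")
        for p in self.output_paths:
            if not (str(p).endswith(".html") or str(p).endswith(".png")):
                raise ValueError(f"output path must end in .html or .png: {p}")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False
    return _Ctx()


def _axis_pipeline(m: DataMatrix, dendro_opt, k_opt, cfg: PipelineConfig,
                   axis: str):
    """Distance, tree, clusters and display order for one axis.

    ``m`` must be oriented so this axis runs along the rows.
    Returns (tree, clusters, order) — any of which may be None.
    """
    if dendro_opt == "none" or m.n_rows < 2:
        return None, None, None
    with _stage(f"{axis} distance"):
        d = compute_distance(m, cfg.dist_method)
    if isinstance(dendro_opt, Dendrogram):
        tree = dendro_opt
        if list(tree.labels) != list(m.row_labels):
            raise PipelineError(
                f"[{axis} dendrogram] supplied tree labels do not match matrix")
    else:
        with _stage(f"{axis} linkage"):
            tree = agglomerate(d, cfg.hclust_method)
    clusters: ClusterAssignment | None = None
    if k_opt == "auto" and m.n_rows >= 3:
        with _stage(f"{axis} find_k"):
            clusters = find_k(d, tree)
    elif isinstance(k_opt, int):
        with _stage(f"{axis} cut_tree"):
            clusters = cut_tree(tree, k_opt)
            if 2 <= k_opt <= m.n_rows - 1:
                clusters.mean_silhouette = mean_silhouette(d, clusters)
    if cfg.seriation_method == "OLO":
        with _stage(f"{axis} seriation"):
            res = olo_reorder(tree, d)
            tree = tree.with_leaf_order(res.order)
    return tree, clusters, tree.leaf_order


def run(m: DataMatrix, cfg: PipelineConfig | None = None) -> FigureBundle:
    """Run the full pipeline on a matrix; write any requested output files.

    Returns the assembled :class:`FigureBundle` (also written to each path
    in ``cfg.output_paths``; extension selects HTML or PNG).
    """
    cfg = cfg or PipelineConfig()
    with _stage("transform"):
        mt = apply_transform(m, cfg.transform)  # type: ignore[arg-type]
    row_tree, row_clusters, row_order = _axis_pipeline(
        mt, cfg.row_dendrogram, cfg.k_row, cfg, "row")
    col_tree, col_clusters, col_order = _axis_pipeline(
        mt.transpose(), cfg.col_dendrogram, cfg.k_col, cfg, "column")
    with _stage("reorder"):
        ordered = apply_order(mt, row_order, col_order)
        # trees carry the same permutation so figure and trees stay aligned
    if isinstance(cfg.scale, ColorScale):
        scale = cfg.scale
    else:
        scale = pick_default_scale(cfg.data_kind)
    with _stage("layout"):
        bundle = build_figure(
            ordered, row_tree=row_tree, col_tree=col_tree,
            row_clusters=row_clusters, col_clusters=col_clusters,
            annotations=_reordered_annotations(cfg.annotations, m, ordered),
            scale=scale, cfg=cfg.layout)
    for path in cfg.output_paths:
        p = str(path)
        with _stage("export"):
            if p.endswith(".html"):
                to_html(bundle, p)
            else:
                to_png(bundle, p, *cfg.png_size)
    return bundle


def _reordered_annotations(tracks: list[AnnotationTrack], original: DataMatrix,
                           ordered: DataMatrix) -> list[AnnotationTrack]:
    """Align annotation categories with the display (post-seriation) order."""
    out = []
    for tr in tracks:
        src = original.row_labels if tr.axis == "row" else original.col_labels
        dst = ordered.row_labels if tr.axis == "row" else ordered.col_labels
        idx = {lab: i for i, lab in enumerate(src)}
        cats = [tr.categories[idx[lab]] for lab in dst]
        out.append(AnnotationTrack(axis=tr.axis, name=tr.name, categories=cats,
                                   level_order=list(tr.level_order)))
    return out
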
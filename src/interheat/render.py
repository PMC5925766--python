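"""Figure assembly and export: standalone interactive HTML and static PNG.

The figure is a tiled matrix of colored cells flanked by optional row/column
dendrograms (branches colored by cluster), categorical annotation sidebars
and a colorbar. The interactive export is a single self-contained HTML file:
the plot is inline SVG and a small embedded script provides hover tooltips,
wheel zoom and drag pan — no external scripts, so the file works offline and
can be shared as-is (e.g. as journal supplementary material).

Export is deterministic: identical inputs produce byte-identical HTML (no
timestamps, no generated ids), which makes outputs diffable and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterAssignment, Dendrogram
from .colors import ColorScale, cluster_colors, value_to_color
from .matrix_io import AnnotationTrack, DataMatrix

__all__ = ["LayoutConfig", "FigureBundle", "RenderError", "build_figure",
           "to_html", "to_png"]

NEUTRAL_BRANCH = "#555555"
DEFAULT_TOOLTIP = "row: {row}<br>column: {col}<br>value: {value}"


class RenderError(ValueError):
    pass


@dataclass
class LayoutConfig:
    """Presentation knobs for the assembled figure."""

    show_row_dendrogram: bool = True
    show_col_dendrogram: bool = True
    tooltip_template: str = DEFAULT_TOOLTIP
    figure_title: str = ""
    colorbar_title: str = ""
    dendrogram_fraction: float = 0.2  # of the heatmap panel size, per axis

    def __post_init__(self) -> None:
        if not 0.0 < self.dendrogram_fraction < 0.5:
            raise RenderError("dendrogram_fraction must lie in (0, 0.5)")


@dataclass
class FigureBundle:
    """Everything needed to draw the figure, resolution-independent.

    Dendrogram segments live in tree coordinates: leaf axis in units of leaf
    positions (leaf i spans [i, i+1], center i+0.5), height axis in merge
    heights. Each segment is (a_leafcoord, a_height, b_leafcoord, b_height,
    hex color).
    """

    cell_colors: list[list[str]]
    tooltips: list[list[str]]
    row_labels: list[str]
    col_labels: list[str]
    scale: ColorScale
    config: LayoutConfig
    row_dendro: list[tuple[float, float, float, float, str]] | None = None
    col_dendro: list[tuple[float, float, float, float, str]] | None = None
    row_annotations: list[tuple[str, list[str], dict[str, str]]] = field(default_factory=list)
    col_annotations: list[tuple[str, list[str], dict[str, str]]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.cell_colors)

    @property
    def n_cols(self) -> int:
        return len(self.cell_colors[0])


def _dendro_segments(t: Dendrogram, clusters: ClusterAssignment | None):
    """Line segments of a dendrogram in tree coordinates, colored by cluster.

    A segment below a cluster's root (i.e. all leaves beneath it belong to
    one cluster) takes that cluster's color; segments above are neutral.
    """
    n = t.n_leaves
    pos = np.empty(n)
    pos[t.leaf_order] = np.arange(n) + 0.5
    x = {i: pos[i] for i in range(n)}
    y = {i: 0.0 for i in range(n)}
    under = t.leaves_under()

    def node_color(node: int) -> str:
        if clusters is None:
            return NEUTRAL_BRANCH
        ids = {int(clusters.labels_by_leaf[leaf]) for leaf in under[node]}
        if len(ids) == 1:
            return cluster_colors(clusters.k)[ids.pop()]
        return NEUTRAL_BRANCH

    segs = []
    for i, (a, b, h, _) in enumerate(t.linkage_matrix):
        a, b = int(a), int(b)
        node = n + i
        xa, xb = x[a], x[b]
        segs.append((xa, y[a], xa, h, node_color(a)))
        segs.append((xb, y[b], xb, h, node_color(b)))
        segs.append((xa, h, xb, h, node_color(node)))
        x[node] = (xa + xb) / 2.0
        y[node] = h
    return segs


def _annotation_panels(tracks: list[AnnotationTrack], labels: list[str], axis: str):
    panels = []
    for tr in tracks:
        if tr.axis != axis:
            continue
        if len(tr.categories) != len(labels):
            raise RenderError(
                f"annotation {tr.name!r} has {len(tr.categories)} entries for "
                f"{len(labels)} {axis}s")
        palette = cluster_colors(len(tr.level_order))
        legend = {lvl: palette[i] for i, lvl in enumerate(tr.level_order)}
        panels.append((tr.name, [legend[c] for c in tr.categories], legend))
    return panels


def _fmt_value(v: float) -> str:
    return "NA" if np.isnan(v) else format(float(v), ".6g")


def build_figure(m: DataMatrix,
                 row_tree: Dendrogram | None = None,
                 col_tree: Dendrogram | None = None,
                 row_clusters: ClusterAssignment | None = None,
                 col_clusters: ClusterAssignment | None = None,
                 annotations: list[AnnotationTrack] | None = None,
                 scale: ColorScale | None = None,
                 cfg: LayoutConfig | None = None) -> FigureBundle:
    """Assemble a figure bundle from a (already leaf-ordered) matrix.

    The matrix must arrive permuted to the dendrogram leaf orders; a label
    mismatch between a tree and the matrix is an error. Row 0 is drawn at
    the top of the heatmap.
    """
    cfg = cfg or LayoutConfig()
    if scale is None:
        from .colors import pick_default_scale
        scale = pick_default_scale("plain")
    if scale.limits is None:
        obs = m.values[~m.missing_mask]
        if obs.size == 0:
            lo, hi = 0.0, 1.0
        else:
            lo, hi = float(obs.min()), float(obs.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        scale = scale.with_limits(lo, hi)
    for tree, labels, axis in ((row_tree, m.row_labels, "row"),
                               (col_tree, m.col_labels, "column")):
        if tree is not None and tree.ordered_labels() != list(labels):
            raise RenderError(
                f"{axis} dendrogram leaf order does not match matrix {axis} labels")
    cell_colors = [[value_to_color(scale, v) for v in row] for row in m.values]
    tooltips = [[cfg.tooltip_template.format(row=m.row_labels[i],
                                             col=m.col_labels[j],
                                             value=_fmt_value(m.values[i, j]))
                 for j in range(m.n_cols)] for i in range(m.n_rows)]
    row_segs = col_segs = None
    if row_tree is not None and cfg.show_row_dendrogram:
        rt = row_tree.with_leaf_order(np.arange(m.n_rows))  # matrix already permuted
        row_segs = _dendro_segments(rt, _permuted(row_clusters, row_tree))
    if col_tree is not None and cfg.show_col_dendrogram:
        ct = col_tree.with_leaf_order(np.arange(m.n_cols))
        col_segs = _dendro_segments(ct, _permuted(col_clusters, col_tree))
    annotations = annotations or []
    return FigureBundle(
        cell_colors=cell_colors, tooltips=tooltips,
        row_labels=list(m.row_labels), col_labels=list(m.col_labels),
        scale=scale, config=cfg, row_dendro=row_segs, col_dendro=col_segs,
        row_annotations=_annotation_panels(annotations, m.row_labels, "row"),
        col_annotations=_annotation_panels(annotations, m.col_labels, "column"),
    )


def _permuted(clusters: ClusterAssignment | None, tree: Dendrogram):
    """Re-index a leaf-indexed cluster assignment to display positions."""
    if clusters is None:
        return None
    # display position i holds original leaf leaf_order[i]
    labels = clusters.labels_by_leaf[tree.leaf_order]
    return ClusterAssignment(clusters.k, labels,
                             mean_silhouette=clusters.mean_silhouette)


# ---------------------------------------------------------------------------
# geometry shared by the HTML and PNG backends

def _geometry(f: FigureBundle):
    n_r, n_c = f.n_rows, f.n_cols
    cw = max(4.0, min(36.0, 680.0 / n_c))
    ch = max(4.0, min(36.0, 520.0 / n_r))
    hm_w, hm_h = cw * n_c, ch * n_r
    frac = f.config.dendrogram_fraction
    dend_w = round(hm_w * frac) if f.row_dendro else 0
    dend_h = round(hm_h * frac) if f.col_dendro else 0
    ann_row_w = 16 * len(f.row_annotations)
    ann_col_h = 16 * len(f.col_annotations)
    title_h = 28 if f.config.figure_title else 0
    label_w = 90 if n_r <= 120 else 0
    label_h = 70 if n_c <= 120 else 0
    margin = 12
    hm_x = margin + dend_w + 4 + ann_row_w
    hm_y = margin + title_h + dend_h + 4 + ann_col_h
    cbar_w = 16
    total_w = hm_x + hm_w + 6 + label_w + 18 + cbar_w + 54 + margin
    total_h = hm_y + hm_h + 6 + label_h + margin
    return dict(cw=cw, ch=ch, hm_w=hm_w, hm_h=hm_h, hm_x=hm_x, hm_y=hm_y,
                dend_w=dend_w, dend_h=dend_h, ann_row_w=ann_row_w,
                ann_col_h=ann_col_h, title_h=title_h, label_w=label_w,
                label_h=label_h, margin=margin, cbar_w=cbar_w,
                total_w=total_w, total_h=total_h)


def _esc(s: str) -> str:
    """Escape text for an HTML attribute (quotes and ampersands only, so
    markup like <br> inside tooltips survives into innerHTML)."""
    return s.replace("&", "&amp;").replace('"', "&quot;")


def _esc_text(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


_JS = """
var svg=document.getElementById('ih-svg');
var tip=document.getElementById('ih-tip');
var vb0=svg.getAttribute('viewBox').split(' ').map(Number);
var vb=vb0.slice();
function setVB(){svg.setAttribute('viewBox',vb.join(' '));}
svg.addEventListener('wheel',function(e){
  e.preventDefault();
  var k=e.deltaY<0?0.85:1/0.85;
  var pt=svg.createSVGPoint();pt.x=e.clientX;pt.y=e.clientY;
  var p=pt.matrixTransform(svg.getScreenCTM().inverse());
  vb[0]=p.x-(p.x-vb[0])*k; vb[1]=p.y-(p.y-vb[1])*k;
  vb[2]*=k; vb[3]*=k; setVB();
},{passive:false});
var drag=null;
svg.addEventListener('mousedown',function(e){drag=[e.clientX,e.clientY,vb[0],vb[1]];});
window.addEventListener('mouseup',function(){drag=null;});
svg.addEventListener('dblclick',function(){vb=vb0.slice();setVB();});
svg.addEventListener('mousemove',function(e){
  if(drag){
    var sc=vb[2]/svg.clientWidth;
    vb[0]=drag[2]-(e.clientX-drag[0])*sc;
    vb[1]=drag[3]-(e.clientY-drag[1])*sc;
    setVB();return;
  }
  var t=e.target.getAttribute('data-tip');
  if(t){
    tip.innerHTML=t;tip.style.display='block';
    tip.style.left=(e.pageX+12)+'px';tip.style.top=(e.pageY+12)+'px';
  }else{tip.style.display='none';}
});
svg.addEventListener('mouseleave',function(){tip.style.display='none';});
"""


def _svg_dendrogram(parts, segs, g, axis):
    """Append dendrogram <line> elements; height axis grows away from the
    heatmap (leftward for rows, upward for columns)."""
    hmax = max((max(s[1], s[3]) for s in segs), default=0.0) or 1.0
    for x1, h1, x2, h2, color in segs:
        if axis == "row":
            px1 = g["hm_x"] - 4 - (h1 / hmax) * g["dend_w"]
            py1 = g["hm_y"] + x1 * g["ch"]
            px2 = g["hm_x"] - 4 - (h2 / hmax) * g["dend_w"]
            py2 = g["hm_y"] + x2 * g["ch"]
        else:
            px1 = g["hm_x"] + x1 * g["cw"]
            py1 = g["hm_y"] - 4 - (h1 / hmax) * g["dend_h"]
            px2 = g["hm_x"] + x2 * g["cw"]
            py2 = g["hm_y"] - 4 - (h2 / hmax) * g["dend_h"]
        parts.append(
            f'<line x1="{px1:.2f}" y1="{py1:.2f}" x2="{px2:.2f}" y2="{py2:.2f}" '
            f'stroke="{color}" stroke-width="1.2"/>')


def render_html(f: FigureBundle) -> str:
    """Render the bundle to a self-contained HTML document string."""
    g = _geometry(f)
    parts: list[str] = []
    parts.append(
        f'<svg id="ih-svg" xmlns="http://www.w3.org/2000/svg" '
        f'width="{g["total_w"]:.0f}" height="{g["total_h"]:.0f}" '
        f'viewBox="0 0 {g["total_w"]:.0f} {g["total_h"]:.0f}" '
        f'style="font-family:sans-serif;background:#ffffff">')
    if f.config.figure_title:
        parts.append(
            f'<text x="{g["total_w"] / 2:.2f}" y="{g["margin"] + 16:.2f}" '
            f'text-anchor="middle" font-size="16">'
            f'{_esc_text(f.config.figure_title)}</text>')
    # heatmap cells
    for i in range(f.n_rows):
        y = g["hm_y"] + i * g["ch"]
        for j in range(f.n_cols):
            x = g["hm_x"] + j * g["cw"]
            parts.append(
                f'<rect x="{x:.2f}" y="{y:.2f}" width="{g["cw"]:.2f}" '
                f'height="{g["ch"]:.2f}" fill="{f.cell_colors[i][j]}" '
                f'data-tip="{_esc(f.tooltips[i][j])}"/>')
    if f.row_dendro:
        _svg_dendrogram(parts, f.row_dendro, g, "row")
    if f.col_dendro:
        _svg_dendrogram(parts, f.col_dendro, g, "column")
    # annotation sidebars
    for t, (name, colors, _) in enumerate(f.row_annotations):
        x = g["hm_x"] - g["ann_row_w"] + 16 * t + 1
        for i, c in enumerate(colors):
            parts.append(
                f'<rect x="{x:.2f}" y="{g["hm_y"] + i * g["ch"]:.2f}" width="14" '
                f'height="{g["ch"]:.2f}" fill="{c}" data-tip="{_esc(name)}"/>')
    for t, (name, colors, _) in enumerate(f.col_annotations):
        y = g["hm_y"] - g["ann_col_h"] + 16 * t + 1
        for j, c in enumerate(colors):
            parts.append(
                f'<rect x="{g["hm_x"] + j * g["cw"]:.2f}" y="{y:.2f}" '
                f'width="{g["cw"]:.2f}" height="14" fill="{c}" '
                f'data-tip="{_esc(name)}"/>')
    # axis labels
    if g["label_w"]:
        for i, lab in enumerate(f.row_labels):
            parts.append(
                f'<text x="{g["hm_x"] + g["hm_w"] + 4:.2f}" '
                f'y="{g["hm_y"] + (i + 0.72) * g["ch"]:.2f}" '
                f'font-size="{min(11, max(6, g["ch"] - 2)):.0f}">'
                f'{_esc_text(lab)}</text>')
    if g["label_h"]:
        for j, lab in enumerate(f.col_labels):
            x = g["hm_x"] + (j + 0.6) * g["cw"]
            y = g["hm_y"] + g["hm_h"] + 8
            parts.append(
                f'<text x="{x:.2f}" y="{y:.2f}" font-size='
                f'"{min(11, max(6, g["cw"] - 2)):.0f}" '
                f'transform="rotate(60 {x:.2f} {y:.2f})">{_esc_text(lab)}</text>')
    # colorbar (64 bands, top = high)
    cb_x = g["total_w"] - g["margin"] - 54 - g["cbar_w"]
    cb_y, cb_h = g["hm_y"], min(g["hm_h"], 220.0)
    lo, hi = f.scale.limits  # type: ignore[misc]
    for b in range(64):
        v = hi - (b + 0.5) / 64 * (hi - lo)
        parts.append(
            f'<rect x="{cb_x:.2f}" y="{cb_y + b * cb_h / 64:.2f}" '
            f'width="{g["cbar_w"]}" height="{cb_h / 64 + 0.5:.2f}" '
            f'fill="{value_to_color(f.scale, v)}"/>')
    for v, frac in ((hi, 0.0), ((lo + hi) / 2, 0.5), (lo, 1.0)):
        parts.append(
            f'<text x="{cb_x + g["cbar_w"] + 4:.2f}" '
            f'y="{cb_y + frac * cb_h + 4:.2f}" font-size="10">'
            f'{format(v, ".4g")}</text>')
    if f.config.colorbar_title:
        parts.append(
            f'<text x="{cb_x:.2f}" y="{cb_y - 8:.2f}" font-size="11">'
            f'{_esc_text(f.config.colorbar_title)}</text>')
    parts.append("</svg>")
    svg = "\n".join(parts)
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset=\"utf-8\"/>\n"
        f"<title>{_esc_text(f.config.figure_title) or 'heatmap'}</title>\n"
        "<style>\n"
        "#ih-tip{position:absolute;display:none;background:#ffffff;"
        "border:1px solid #888;padding:4px 6px;font:12px sans-serif;"
        "pointer-events:none;box-shadow:1px 1px 3px rgba(0,0,0,0.3);}\n"
        "body{margin:8px;}\n"
        "</style>\n</head>\n<body>\n"
        f"{svg}\n"
        '<div id="ih-tip"></div>\n'
        f"<script>{_JS}</script>\n"
        "</body>\n</html>\n")


def to_html(f: FigureBundle, path) -> None:
    """Write the bundle as one self-contained HTML file (offline-viewable)."""
    html = render_html(f)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(html)


def to_png(f: FigureBundle, path, width_px: int = 900, height_px: int = 700) -> None:
    """Write a static PNG of the same layout at exactly the requested size."""
    if width_px <= 0 or height_px <= 0:
        raise RenderError("PNG dimensions must be positive")
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "static PNG export requires matplotlib; install it with "
            "'pip install matplotlib'") from exc

    g = _geometry(f)
    W, H = float(g["total_w"]), float(g["total_h"])
    dpi = 100.0
    # quarter-pixel nudge so float truncation cannot drop the last pixel row
    fig = plt.figure(figsize=((width_px + 0.25) / dpi, (height_px + 0.25) / dpi),
                     dpi=dpi)

    def ax_at(x, y, w, h):
        # pixel geometry -> figure fraction (y measured from the top)
        return fig.add_axes([x / W, 1.0 - (y + h) / H, w / W, h / H])

    rgb = np.array([[_hex_to_rgb01(c) for c in row] for row in f.cell_colors])
    ax = ax_at(g["hm_x"], g["hm_y"], g["hm_w"], g["hm_h"])
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    for axis, segs, size in (("row", f.row_dendro, g["dend_w"]),
                             ("column", f.col_dendro, g["dend_h"])):
        if not segs:
            continue
        hmax = max(max(s[1], s[3]) for s in segs) or 1.0
        if axis == "row":
            dax = ax_at(g["hm_x"] - 4 - size, g["hm_y"], size, g["hm_h"])
            lines = [[(h1 / hmax, x1), (h2 / hmax, x2)] for x1, h1, x2, h2, _ in segs]
            dax.set_xlim(1, 0), dax.set_ylim(f.n_rows, 0)
        else:
            dax = ax_at(g["hm_x"], g["hm_y"] - 4 - size, g["hm_w"], size)
            lines = [[(x1, h1 / hmax), (x2, h2 / hmax)] for x1, h1, x2, h2, _ in segs]
            dax.set_xlim(0, f.n_cols), dax.set_ylim(0, 1)
        dax.add_collection(LineCollection(lines, colors=[s[4] for s in segs],
                                          linewidths=1.2))
        dax.axis("off")
    for t, (name, colors, _) in enumerate(f.row_annotations):
        aax = ax_at(g["hm_x"] - g["ann_row_w"] + 16 * t + 1, g["hm_y"], 14, g["hm_h"])
        aax.imshow(np.array([[_hex_to_rgb01(c)] for c in colors]),
                   aspect="auto", interpolation="nearest")
        aax.axis("off")
    for t, (name, colors, _) in enumerate(f.col_annotations):
        aax = ax_at(g["hm_x"], g["hm_y"] - g["ann_col_h"] + 16 * t + 1, g["hm_w"], 14)
        aax.imshow(np.array([[_hex_to_rgb01(c) for c in colors]]),
                   aspect="auto", interpolation="nearest")
        aax.axis("off")
    if g["label_w"]:
        for i, lab in enumerate(f.row_labels):
            ax.text(1.005, 1.0 - (i + 0.5) / f.n_rows, lab, transform=ax.transAxes,
                    fontsize=6, va="center")
    if g["label_h"]:
        for j, lab in enumerate(f.col_labels):
            ax.text((j + 0.5) / f.n_cols, -0.01, lab, transform=ax.transAxes,
                    fontsize=6, va="top", ha="right", rotation=60)
    # colorbar
    lo, hi = f.scale.limits  # type: ignore[misc]
    cb_x = W - g["margin"] - 54 - g["cbar_w"]
    cax = ax_at(cb_x, g["hm_y"], g["cbar_w"], min(g["hm_h"], 220.0))
    grad = np.array([[_hex_to_rgb01(value_to_color(f.scale, hi - (b + 0.5) / 64 * (hi - lo)))]
                     for b in range(64)])
    cax.imshow(grad, aspect="auto", interpolation="nearest")
    cax.set_xticks([])
    cax.set_yticks([0, 63])
    cax.set_yticklabels([format(hi, ".4g"), format(lo, ".4g")], fontsize=7)
    cax.yaxis.tick_right()
    if f.config.colorbar_title:
        cax.set_title(f.config.colorbar_title, fontsize=8)
    if f.config.figure_title:
        fig.suptitle(f.config.figure_title, fontsize=12)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def _hex_to_rgb01(h: str) -> tuple[float, float, float]:
    h = h.lstrip("#")
    return (int(h[0:2], 16) / 255.0, int(h[2:4], 16) / 255.0,
            int(h[4:6], 16) / 255.0)
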
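"""Value-to-color mapping for heatmap cells, cluster branches and annotations.

A good heatmap palette should be colorful (wide range), perceptually uniform
(nearby values get nearby-looking colors, uniformly across the range) and
robust to common color-vision deficiencies. The sequential default here is
the viridis palette, which balances all three. For signed quantities with a
meaningful zero — correlation matrices above all — a divergent scale with a
neutral midpoint and symmetric limits (-1, 1) is preferred, so the two ends
of the range stay visually distinct.

Palette stop tables are fixed hex constants sampled from matplotlib's
colormaps (viridis; Moreland's cool-warm; ColorBrewer RdBu/BrBG/RdYlBu).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColorScale",
    "PALETTES",
    "value_to_color",
    "cluster_colors",
    "pick_default_scale",
    "relative_luminance",
]

# 11-stop viridis (sequential, perceptually uniform, colorblind-safe)
_VIRIDIS = ["#440154", "#482475", "#414487", "#355f8d", "#2a788e", "#21918c",
            "#22a884", "#44bf70", "#7ad151", "#bddf26", "#fde725"]
# 9-stop Moreland cool-warm (divergent, neutral center)
_COOL_WARM = ["#3b4cc0", "#6282ea", "#8db0fe", "#b9d0f9", "#dddcdc",
              "#f5c4ac", "#f4987a", "#dd5f4b", "#b40426"]
# ColorBrewer 11-class divergent alternates
_RDBU = ["#67001f", "#b1182b", "#d6604d", "#f3a481", "#fddbc7", "#f6f7f7",
         "#d1e5f0", "#90c4dd", "#4393c3", "#2065ab", "#053061"]
_BRBG = ["#543005", "#8b500a", "#bf812d", "#dec17b", "#f6e8c3", "#f4f5f5",
         "#c7eae5", "#7fccc0", "#35978f", "#01655d", "#003c30"]
_RDYLBU = ["#a50026", "#d62f27", "#f46d43", "#fdad60", "#fee090", "#feffc0",
           "#e0f3f8", "#aad8e9", "#74add1", "#4574b3", "#313695"]

# first appearance along the leaf order picks colors from the front
_CATEGORICAL = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


def _stops(hexes: list[str]) -> list[tuple[float, str]]:
    k = len(hexes)
    return [(i / (k - 1), h) for i, h in enumerate(hexes)]


PALETTES: dict[str, tuple[str, list[tuple[float, str]]]] = {
    "viridis": ("sequential", _stops(_VIRIDIS)),
    "cool-warm": ("divergent", _stops(_COOL_WARM)),
    "rdbu": ("divergent", _stops(_RDBU)),
    "brbg": ("divergent", _stops(_BRBG)),
    "rdylbu": ("divergent", _stops(_RDYLBU)),
}


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)


def _rgb_to_hex(r: float, g: float, b: float) -> str:
    return "#{:02x}{:02x}{:02x}".format(
        int(round(r)), int(round(g)), int(round(b)))


def relative_luminance(hex_color: str) -> float:
    """WCAG relative luminance of an sRGB hex color, in [0, 1]."""
    def chan(c: int) -> float:
        c_ = c / 255.0
        return c_ / 12.92 if c_ <= 0.03928 else ((c_ + 0.055) / 1.055) ** 2.4
    r, g, b = _hex_to_rgb(hex_color)
    return 0.2126 * chan(r) + 0.7152 * chan(g) + 0.0722 * chan(b)


@dataclass
class ColorScale:
    """A palette with limits and a missing-value color.

    ``stops`` are (position, hex) pairs with strictly increasing positions
    from 0 to 1. ``limits`` of None means automatic (data min/max, filled in
    by the pipeline before rendering).
    """

    kind: str  # "sequential" | "divergent"
    stops: list[tuple[float, str]]
    limits: tuple[float, float] | None = None
    na_color: str = "#808080"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sequential", "divergent"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        pos = [p for p, _ in self.stops]
        if len(pos) < 2 or pos[0] != 0.0 or pos[-1] != 1.0 or \
                any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("stop positions must increase strictly from 0 to 1")
        if self.limits is not None:
            lo, hi = self.limits
            if not lo < hi:
                raise ValueError(f"limits must satisfy lo < hi, got {self.limits}")

    def with_limits(self, lo: float, hi: float) -> "ColorScale":
        return ColorScale(self.kind, list(self.stops), (lo, hi),
                          self.na_color, self.name)


def value_to_color(s: ColorScale, v) -> str:
    """Map one value to a hex color (missing -> the scale's NA color).

    The value is clamped to the limits, mapped to a position in [0, 1] and
    colored by piecewise-linear RGB interpolation between bracketing stops.
    """
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return s.na_color
    if s.limits is None:
        raise ValueError("color scale limits are unset; call with_limits first")
    lo, hi = s.limits
    p = (min(max(float(v), lo), hi) - lo) / (hi - lo)
    positions = [q for q, _ in s.stops]
    j = int(np.searchsorted(positions, p, side="right"))
    if j <= 0:
        return s.stops[0][1]
    if j >= len(positions):
        return s.stops[-1][1]
    p0, c0 = s.stops[j - 1]
    p1, c1 = s.stops[j]
    f = (p - p0) / (p1 - p0)
    r0, g0, b0 = _hex_to_rgb(c0)
    r1, g1, b1 = _hex_to_rgb(c1)
    return _rgb_to_hex(r0 + f * (r1 - r0), g0 + f * (g1 - g0), b0 + f * (b1 - b0))


def cluster_colors(k: int) -> list[str]:
    """k maximally-distinct categorical colors; deterministic per k.

    The first ten come from a fixed qualitative table; beyond that, extra
    colors are generated on an evenly spaced hue wheel.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = list(_CATEGORICAL[:k])
    for i in range(len(out), k):
        h = (i - len(_CATEGORICAL)) / max(k - len(_CATEGORICAL), 1)
        r, g, b = colorsys.hsv_to_rgb(h, 0.55, 0.75)
        out.append(_rgb_to_hex(r * 255, g * 255, b * 255))
    return out


def pick_default_scale(data_kind: str = "plain") -> ColorScale:
    """Default scale: sequential viridis for plain data (automatic limits);
    divergent cool-warm with limits (-1, 1) for correlation matrices."""
    if data_kind == "plain":
        kind, stops = PALETTES["viridis"]
        return ColorScale(kind, stops, limits=None, name="viridis")
    if data_kind == "correlation":
        kind, stops = PALETTES["cool-warm"]
        return ColorScale(kind, stops, limits=(-1.0, 1.0), name="cool-warm")
    raise ValueError(f"data_kind must be 'plain' or 'correlation', got {data_kind!r}")
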
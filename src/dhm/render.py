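"""SVG rendering and Circos-format export of dendritic heat maps.

The native output is a self-contained SVG 1.1 file: one annular sector
per (ring, cluster), rings drawn inner to outer by ascending cutoff,
plus the key wedge at 0 degrees split radially into the two darkest
palette extremes. Angles run clockwise from 12 o'clock. Output is
deterministic: identical inputs produce byte-identical files.

For users of the Circos plotting package the same geometry can be
exported as text input files (a karyotype sized by base-ring cluster
abundance plus one heat-map track per ring); Circos itself is never
invoked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .colormap import Palette, default_palette
from .layout import DHMLayout

__all__ = ["RenderConfig", "render_svg", "export_circos"]


@dataclass(frozen=True)
class RenderConfig:
    size: int = 800  # canvas pixels (square)
    stroke_min: float = 0.25  # minimum visible stroke for sub-pixel sectors
    margin: float = 10.0

    def __post_init__(self) -> None:
        if self.size < 50:
            raise ValueError("canvas size must be at least 50 px")


def _polar(cx: float, cy: float, radius: float, angle_deg: float) -> tuple[float, float]:
    """Clockwise-from-12-o'clock polar to SVG coordinates."""
    a = math.radians(angle_deg)
    return cx + radius * math.sin(a), cy - radius * math.cos(a)


def _sector_path(
    cx: float, cy: float, r_in: float, r_out: float, start: float, extent: float
) -> str:
    """SVG path for an annular sector spanning [start, start+extent] degrees."""
    end = start + extent
    large = 1 if extent > 180 else 0
    x0, y0 = _polar(cx, cy, r_out, start)
    x1, y1 = _polar(cx, cy, r_out, end)
    x2, y2 = _polar(cx, cy, r_in, end)
    x3, y3 = _polar(cx, cy, r_in, start)
    return (
        f"M {x0:.4f} {y0:.4f} "
        f"A {r_out:.4f} {r_out:.4f} 0 {large} 1 {x1:.4f} {y1:.4f} "
        f"L {x2:.4f} {y2:.4f} "
        f"A {r_in:.4f} {r_in:.4f} 0 {large} 0 {x3:.4f} {y3:.4f} Z"
    )


def render_svg(
    layout: DHMLayout,
    colours: Mapping[tuple[int, int], str],
    path: str | Path,
    config: Optional[RenderConfig] = None,
    palette: Optional[Palette] = None,
) -> None:
    """Write the DHM as a well-formed SVG file.

    ``colours`` maps (level, cluster index within the ladder ring) to a
    fill colour; a missing entry is an error naming the cluster. The key
    wedge is drawn radially split: inner half darkest red (+11), outer
    half darkest blue (-11).
    """
    config = RenderConfig() if config is None else config
    palette = default_palette() if palette is None else palette
    cx = cy = config.size / 2.0
    r_max = config.size / 2.0 - config.margin
    r0 = layout.inner_radius * r_max
    thick = layout.ring_thickness * r_max

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{config.size}" height="{config.size}" '
        f'viewBox="0 0 {config.size} {config.size}">',
        f'<!-- dendritic heat map: {len(layout.rings)} rings, cutoffs '
        f"{layout.cutoffs[0]} to {layout.cutoffs[-1]} -->",
    ]
    for level, ring in enumerate(layout.rings):
        r_in = r0 + level * thick
        r_out = r_in + thick
        parts.append(f'<g id="ring-{level}" data-cutoff="{layout.cutoffs[level]}">')
        for sector in ring:
            key = (sector.level, sector.cluster_index)
            if key not in colours:
                raise KeyError(
                    f"no colour for cluster {sector.cluster_index} "
                    f"at level {sector.level}"
                )
            fill = colours[key]
            d = _sector_path(cx, cy, r_in, r_out, sector.span.start, sector.span.extent)
            arc_px = r_out * math.radians(sector.span.extent)
            stroke = (
                f' stroke="{fill}" stroke-width="{config.stroke_min}"'
                if arc_px < config.stroke_min
                else ""
            )
            parts.append(
                f'<path id="r{level}c{sector.cluster_index}" class="sector" '
                f'd="{d}" fill="{fill}"{stroke} '
                f'data-start="{sector.span.start:.6f}" '
                f'data-extent="{sector.span.extent:.6f}"/>'
            )
        parts.append("</g>")

    # key wedge: radial split into the two palette extremes
    r_total = r0 + len(layout.rings) * thick
    r_mid = (r0 + r_total) / 2.0
    w_start = layout.wedge.start
    w_ext = layout.wedge.extent
    parts.append('<g id="key-wedge">')
    parts.append(
        f'<path class="wedge" d="{_sector_path(cx, cy, r0, r_mid, w_start, w_ext)}" '
        f'fill="{palette.key_max}"/>'
    )
    parts.append(
        f'<path class="wedge" d="{_sector_path(cx, cy, r_mid, r_total, w_start, w_ext)}" '
        f'fill="{palette.key_min}"/>'
    )
    parts.append("</g>")
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


def export_circos(
    layout: DHMLayout,
    responses: Mapping[tuple[int, int], float],
    out_dir: str | Path,
) -> list[Path]:
    """Write Circos-ready input files for the layout.

    Produces a karyotype with one segment per base-ring cluster (sized
    by its layout weight), one 4-column heat-map track file per ring
    (``segment start end value`` in base-ring coordinate units) and a
    functional circos.conf template referencing them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    base = layout.rings[0]
    # segment length in integer units proportional to angular extent
    seg_len = {
        s.cluster_index: max(1, round(s.span.extent * 1000)) for s in base
    }
    karyotype = out_dir / "karyotype.txt"
    with open(karyotype, "w") as fh:
        for s in base:
            fh.write(
                f"chr - seg{s.cluster_index} seg{s.cluster_index} 0 "
                f"{seg_len[s.cluster_index]} grey\n"
            )
    written.append(karyotype)

    base_spans = [(s.cluster_index, s.span) for s in base]

    def locate(start: float) -> tuple[int, float, float]:
        for k, span in base_spans:
            if span.start - 1e-6 <= start < span.end + 1e-6:
                return k, span.start, span.extent
        raise ValueError(f"angle {start} outside every base-ring span")

    track_paths = []
    for level, ring in enumerate(layout.rings):
        track = out_dir / f"heatmap_ring_{level:02d}.txt"
        with open(track, "w") as fh:
            for s in ring:
                k, b_start, b_extent = locate(s.span.start)
                units = seg_len[k]
                lo = round((s.span.start - b_start) / b_extent * units)
                hi = round((s.span.end - b_start) / b_extent * units)
                hi = max(hi, lo + 1)
                fh.write(
                    f"seg{k} {lo} {hi} {responses[(s.level, s.cluster_index)]:.6f}\n"
                )
        track_paths.append(track)
        written.append(track)

    conf = out_dir / "circos.conf"
    n = len(layout.rings)
    with open(conf, "w") as fh:
        fh.write("# circos configuration template (generated)\n")
        fh.write("karyotype = karyotype.txt\n\n<plots>\n")
        for level, track in enumerate(track_paths):
            r_in = layout.inner_radius + level * layout.ring_thickness
            r_out = r_in + layout.ring_thickness
            fh.write("<plot>\ntype = heatmap\n")
            fh.write(f"file = {track.name}\n")
            fh.write(f"r0 = {r_in:.4f}r\nr1 = {r_out:.4f}r\n</plot>\n")
        fh.write("</plots>\n")
        fh.write("<ideogram>\nshow = no\n</ideogram>\n")
        fh.write("<image>\n<<include etc/image.conf>>\n</image>\n")
        fh.write("<<include etc/colors_fonts_patterns.conf>>\n")
        fh.write("<<include etc/housekeeping.conf>>\n")
    written.append(conf)
    return written
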
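"""Log-ratio bin responses and the 23-category red-white-blue palette.

Each cluster's heat-map value (its *bin response*) is
``r = log10((Group1 + 1) / (Group2 + 1))`` of its group abundances: the
+1 smoothing keeps the ratio finite, and the log keeps small clusters
with an interesting skew visible next to very large ones. Positive r
(GROUP1 excess, GC <= 50%) maps to reds, negative to blues, and exactly
r = 0 to white, giving 23 possible categories: two sequential 11-colour
ramps plus the neutral white.

The normalisation scale M is the largest |r| over a whole figure set —
when several DHM panels are shown together M is shared across panels, so
equal hues mean equal responses everywhere. |r| = M maps to the darkest
category (+-11), the extremes shown in the key wedge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .cluster import ClusterLadder

__all__ = [
    "Palette",
    "default_palette",
    "bin_response",
    "normalization_scale",
    "category_of",
    "color_of",
    "ladder_responses",
    "colour_ladder",
]


def _interp_ramp(start: tuple[int, int, int], end: tuple[int, int, int], n: int) -> tuple[str, ...]:
    ramp = []
    for k in range(n):
        t = k / (n - 1)
        rgb = tuple(round(s + t * (e - s)) for s, e in zip(start, end))
        ramp.append("#{:02X}{:02X}{:02X}".format(*rgb))
    return tuple(ramp)


@dataclass(frozen=True)
class Palette:
    """23 colours: 11 reds and 11 blues (light to dark) around white."""

    reds: tuple[str, ...]
    blues: tuple[str, ...]
    neutral: str = "#FFFFFF"

    def __post_init__(self) -> None:
        if len(self.reds) != 11 or len(self.blues) != 11:
            raise ValueError("palette needs 11 reds and 11 blues")
        if len({*self.reds, *self.blues, self.neutral}) != 23:
            raise ValueError("palette colours must be 23 distinct values")

    @property
    def key_max(self) -> str:
        """Darkest red — the +11 (strongest GROUP1) extreme."""
        return self.reds[-1]

    @property
    def key_min(self) -> str:
        """Darkest blue — the -11 (strongest GROUP2) extreme."""
        return self.blues[-1]


def default_palette() -> Palette:
    """Sequential ramps from near-white to deep red / deep blue.

    Linear RGB interpolation between Brewer-inspired endpoints
    (#FFF5F0 -> #67001F and #F7FBFF -> #053061); any 2x11 ramp can be
    substituted via the pipeline configuration.
    """
    return Palette(
        reds=_interp_ramp((0xFF, 0xF5, 0xF0), (0x67, 0x00, 0x1F), 11),
        blues=_interp_ramp((0xF7, 0xFB, 0xFF), (0x05, 0x30, 0x61), 11),
    )


def bin_response(g1: int, g2: int) -> float:
    """log10((g1 + 1) / (g2 + 1)) — finite for all non-negative counts."""
    if g1 < 0 or g2 < 0:
        raise ValueError("group counts must be non-negative")
    return math.log10((g1 + 1) / (g2 + 1))


def normalization_scale(responses: Iterable[float]) -> float:
    """Largest |r| over all supplied responses (pass every panel of a
    figure set at once to share hues between panels)."""
    scale = None
    for r in responses:
        a = abs(r)
        if scale is None or a > scale:
            scale = a
    if scale is None:
        raise ValueError("normalization_scale: empty response collection")
    return scale


def category_of(r: float, M: float) -> int:
    """Colour category in [-11, +11] for response r under scale M.

    0 iff r = 0 (or the whole map is neutral, M = 0); otherwise
    ``sign(r) * min(11, floor(|r| / M * 11) + 1)``, so only exact
    neutrality is white and |r| = M hits the darkest extreme.
    """
    if M < 0:
        raise ValueError("scale M must be non-negative")
    if r == 0 or M == 0:
        if abs(r) > M:
            raise ValueError(f"|r| = {abs(r)} exceeds scale M = {M}")
        return 0
    if abs(r) > M * (1 + 1e-12):
        raise ValueError(f"|r| = {abs(r)} exceeds scale M = {M}")
    mag = min(11, int(abs(r) / M * 11) + 1)
    return mag if r > 0 else -mag


def color_of(category: int, palette: Optional[Palette] = None) -> str:
    """Hex colour for a category: 0 -> white, +k -> reds[k-1], -k -> blues[k-1]."""
    palette = default_palette() if palette is None else palette
    if not -11 <= category <= 11:
        raise ValueError(f"category {category} outside [-11, 11]")
    if category == 0:
        return palette.neutral
    return palette.reds[category - 1] if category > 0 else palette.blues[-category - 1]


def ladder_responses(ladder: ClusterLadder) -> dict[tuple[int, int], float]:
    """Bin response of every cluster, keyed by (level, cluster index)."""
    return {
        (level, k): bin_response(cl.g1, cl.g2)
        for level, ring in enumerate(ladder.rings)
        for k, cl in enumerate(ring.clusters)
    }


def colour_ladder(
    ladder: ClusterLadder,
    M: Optional[float] = None,
    palette: Optional[Palette] = None,
) -> tuple[dict[tuple[int, int], str], float]:
    """Colours for every cluster of a ladder; returns (colours, M used).

    With ``M`` omitted the scale is this panel's own maximum |r|; pass a
    shared M to keep hues comparable across a figure set.
    """
    palette = default_palette() if palette is None else palette
    responses = ladder_responses(ladder)
    if M is None:
        M = normalization_scale(responses.values())
    colours = {
        key: color_of(category_of(r, M), palette) for key, r in responses.items()
    }
    return colours, M
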
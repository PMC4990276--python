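"""Ring geometry for dendritic heat maps.

Each cutoff level of a cluster ladder becomes one ring of annular
sectors. Angles are measured clockwise from 12 o'clock = 0 degrees. A
key wedge (default 12 degrees) is centred at 0 degrees; the remaining
``360 - wedge`` degrees are shared by the clusters of each ring,
proportionally to cluster abundance (or unique-sequence count), starting
clockwise from the wedge's end.

Because child abundances sum exactly to their parent's, each deeper ring
partitions every parent's span among its children, so the angular range
of any sequence is conserved from the innermost ring out to the
circumference — the dendrogram-like alignment of the figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cluster import Cluster, ClusterLadder, RingPartition

__all__ = ["AngularSpan", "RingSector", "DHMLayout", "LayoutConfig",
           "order_ring_clusters", "assign_spans", "build_layout"]


@dataclass(frozen=True)
class AngularSpan:
    """Arc on the circle: start angle in [0, 360) degrees, extent > 0."""

    start: float
    extent: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < 360:
            raise ValueError("start must be in [0, 360)")
        if not 0 < self.extent <= 360:
            raise ValueError("extent must be in (0, 360]")

    @property
    def end(self) -> float:
        return self.start + self.extent

    def contains(self, other: "AngularSpan", tol: float = 1e-6) -> bool:
        return (
            other.start >= self.start - tol and other.end <= self.end + tol
        )


@dataclass(frozen=True)
class RingSector:
    """One laid-out cluster: its ring level, its index within the
    ladder's ring (the colour key), and its angular span."""

    level: int
    cluster_index: int
    cluster: Cluster
    span: AngularSpan


@dataclass
class DHMLayout:
    """Geometry of one dendritic heat map.

    ``rings[level]`` lists sectors in angular order; ``wedge`` is the key
    wedge centred at 0 degrees; radii are relative units (outer radius 1).
    """

    rings: list[list[RingSector]]
    wedge: AngularSpan
    cutoffs: tuple[float, ...]
    inner_radius: float
    ring_thickness: float


@dataclass(frozen=True)
class LayoutConfig:
    wedge_extent: float = 12.0  # degrees
    inner_radius_frac: float = 0.15  # of the outer radius
    width_by: str = "abundance"  # or "unique"

    def __post_init__(self) -> None:
        if not 0 < self.wedge_extent <= 90:
            raise ValueError("wedge_extent must be in (0, 90] degrees")
        if not 0 < self.inner_radius_frac < 1:
            raise ValueError("inner_radius_frac must be in (0, 1)")
        if self.width_by not in ("abundance", "unique"):
            raise ValueError("width_by must be 'abundance' or 'unique'")


def _weight(cluster: Cluster, width_by: str) -> int:
    return cluster.abundance if width_by == "abundance" else len(cluster.members)


def order_ring_clusters(
    ring: RingPartition,
    order: Sequence[int],
    parents: Optional[Sequence[Optional[int]]] = None,
    parent_order: Optional[Sequence[int]] = None,
) -> list[int]:
    """Angular order of a ring's clusters (as indices into the ring).

    Base ring: clusters sorted by the minimum guide-order rank of their
    members. Deeper rings: children grouped under their parent in the
    parent's angular order, and sorted by minimum rank within a parent —
    children of distinct parents never interleave.
    """
    rank = {idx: pos for pos, idx in enumerate(order)}

    def min_rank(k: int) -> int:
        return min(rank[m] for m in ring.clusters[k].members)

    ks = list(range(len(ring.clusters)))
    if parents is None or parent_order is None:
        return sorted(ks, key=min_rank)
    parent_pos = {p: i for i, p in enumerate(parent_order)}
    return sorted(ks, key=lambda k: (parent_pos[parents[k]], min_rank(k)))


def assign_spans(
    ordered_rings: Sequence[Sequence[tuple[int, Cluster]]],
    parents_by_level: Sequence[Sequence[Optional[int]]],
    wedge_extent: float,
    width_by: str = "abundance",
) -> tuple[list[list[AngularSpan]], AngularSpan]:
    """Count-proportional spans with parent-range conservation.

    ``ordered_rings[level]`` holds (cluster_index, cluster) pairs in
    angular order. The base ring divides ``360 - wedge_extent`` degrees
    (starting clockwise from the wedge's end at ``wedge_extent / 2``)
    proportionally to cluster weight; each deeper ring divides every
    parent's span among its children, again proportionally.
    """
    avail = 360.0 - wedge_extent
    wedge = AngularSpan(start=360.0 - wedge_extent / 2.0, extent=wedge_extent)
    base = ordered_rings[0]
    total = sum(_weight(c, width_by) for _, c in base)
    if total <= 0:
        raise ValueError("zero total abundance")
    spans_by_level: list[list[AngularSpan]] = []
    spans_by_index: list[dict[int, AngularSpan]] = []

    cursor = wedge_extent / 2.0
    base_spans: dict[int, AngularSpan] = {}
    ordered0: list[AngularSpan] = []
    for k, cl in base:
        extent = avail * _weight(cl, width_by) / total
        span = AngularSpan(start=cursor, extent=extent)
        base_spans[k] = span
        ordered0.append(span)
        cursor += extent
    spans_by_level.append(ordered0)
    spans_by_index.append(base_spans)

    for level in range(1, len(ordered_rings)):
        prev = spans_by_index[level - 1]
        parents = parents_by_level[level]
        # children arrive grouped by parent and in parent order
        cursors = {p: prev[p].start for p in prev}
        level_spans: list[AngularSpan] = []
        index_spans: dict[int, AngularSpan] = {}
        parent_weight: dict[int, int] = {}
        for k, cl in ordered_rings[level]:
            p = parents[k]
            assert p is not None
            parent_weight[p] = parent_weight.get(p, 0) + _weight(cl, width_by)
        for k, cl in ordered_rings[level]:
            p = parents[k]
            assert p is not None
            extent = prev[p].extent * _weight(cl, width_by) / parent_weight[p]
            span = AngularSpan(start=cursors[p], extent=extent)
            cursors[p] += extent
            level_spans.append(span)
            index_spans[k] = span
        spans_by_level.append(level_spans)
        spans_by_index.append(index_spans)
    return spans_by_level, wedge


def build_layout(
    ladder: ClusterLadder,
    order: Sequence[int],
    config: Optional[LayoutConfig] = None,
) -> DHMLayout:
    """Full DHM geometry: innermost ring = lowest cutoff, outermost = 1.0."""
    config = LayoutConfig() if config is None else config
    ordered_rings: list[list[tuple[int, Cluster]]] = []
    angular_orders: list[list[int]] = []
    for level, ring in enumerate(ladder.rings):
        if level == 0:
            ks = order_ring_clusters(ring, order)
        else:
            ks = order_ring_clusters(
                ring, order, ladder.parent_of[level], angular_orders[level - 1]
            )
        angular_orders.append(ks)
        ordered_rings.append([(k, ring.clusters[k]) for k in ks])
    spans_by_level, wedge = assign_spans(
        ordered_rings, ladder.parent_of, config.wedge_extent, config.width_by
    )
    n_rings = len(ladder.rings)
    thickness = (1.0 - config.inner_radius_frac) / n_rings
    rings = [
        [
            RingSector(level=level, cluster_index=k, cluster=cl, span=span)
            for (k, cl), span in zip(ordered_rings[level], spans_by_level[level])
        ]
        for level in range(n_rings)
    ]
    return DHMLayout(
        rings=rings,
        wedge=wedge,
        cutoffs=ladder.cutoffs,
        inner_radius=config.inner_radius_frac,
        ring_thickness=thickness,
    )
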
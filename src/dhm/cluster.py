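"""Nested cluster ladders over a range of identity cutoffs.

A *cluster ladder* is the skeleton of a dendritic heat map: one partition
of the sequence set per identity cutoff (default 0.75, 0.76, ..., 1.00),
with every cluster at a level nested inside exactly one cluster of the
level below. Two families of methods build ladders:

* **Bottom-up (agglomerative)** — a single merge tree under min, max or
  avg linkage is cut at each cutoff. A merge applies at a cutoff when its
  linkage identity meets the cutoff (``>=`` semantics, matching the
  minimum-identity reading of an identity threshold). Because all three
  linkages are monotone, the 26 cuts of one tree coincide with 26
  independent per-cutoff runs while guaranteeing nesting.

* **Top-down (divisive, centroid-based)** — greedy centroid clustering
  in the staggered guide order at the lowest cutoff, then each cluster is
  independently re-partitioned at the next cutoff using the staggered
  order restricted to its members, stepwise up to 1.0. Each sequence
  either joins the existing centroid of highest identity at or above the
  cutoff or founds a new cluster as its own centroid.

Cluster group tallies (``g1``/``g2``) sum dereplicated abundance counts,
so collapsed duplicates still weight heat-map colours and widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _agglo, _codec
from ._agglo import MergeStep
from .identity import IdentityMatrix, guide_order, identity_matrix, pairwise_identity, staggered_order
from .seqio import GroupLabel, SeqRecord

__all__ = [
    "CUTOFF_EPS",
    "default_cutoffs",
    "Cluster",
    "RingPartition",
    "MergeTree",
    "ClusterLadder",
    "agglomerative_merge_tree",
    "cut_at",
    "build_agglomerative_ladder",
    "greedy_centroid_partition",
    "build_divisive_ladder",
    "write_ladder",
    "read_ladder",
]

#: numerical slack when comparing a floating identity against a cutoff;
#: identities are ratios of small integers, so 1e-9 separates genuine
#: boundary hits from float rounding without conflating distinct values
CUTOFF_EPS = 1e-9

METHODS = ("min", "max", "avg", "centroid")


def default_cutoffs(lo: float = 0.75, hi: float = 1.0, step: float = 0.01) -> tuple[float, ...]:
    """Strictly increasing cutoff ladder (defaults: 26 levels, step 0.01)."""
    n_steps = int(round((hi - lo) / step))
    cutoffs = tuple(round(lo + k * step, 10) for k in range(n_steps + 1))
    if any(c <= 0 or c > 1 for c in cutoffs) or any(
        b <= a for a, b in zip(cutoffs, cutoffs[1:])
    ):
        raise ValueError("cutoffs must be strictly increasing within (0, 1]")
    return cutoffs


@dataclass(frozen=True)
class Cluster:
    """A cluster of record indices with group abundance tallies.

    ``centroid`` is set by the divisive method only and is always a
    member; ``g1 + g2`` equals the summed abundance of the members.
    """

    members: tuple[int, ...]
    g1: int
    g2: int
    centroid: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.centroid is not None and self.centroid not in self.members:
            raise ValueError("centroid must be a member of its cluster")

    @property
    def abundance(self) -> int:
        return self.g1 + self.g2


@dataclass(frozen=True)
class RingPartition:
    """The partition at one cutoff: disjoint clusters covering all indices."""

    cutoff: float
    clusters: tuple[Cluster, ...]

    def member_sets(self) -> list[frozenset[int]]:
        return [frozenset(c.members) for c in self.clusters]


@dataclass(frozen=True)
class MergeTree:
    """Merge sequence of an agglomerative run.

    ``merges`` holds n-1 steps in merge order; linkage identities are
    non-increasing along the sequence (linkage monotonicity), which is
    what makes per-cutoff cuts nest.
    """

    n_leaves: int
    linkage: str
    merges: tuple[MergeStep, ...]


@dataclass
class ClusterLadder:
    """One RingPartition per cutoff (ascending) with parent links.

    ``parent_of[level][k]`` is the index of the cluster at ``level - 1``
    containing cluster k of ``level`` (None throughout level 0).
    """

    method: str
    cutoffs: tuple[float, ...]
    rings: list[RingPartition]
    parent_of: list[list[Optional[int]]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return sum(len(c.members) for c in self.rings[0].clusters)


def _group_tallies(
    members: Sequence[int], records: Sequence[SeqRecord]
) -> tuple[int, int]:
    g1 = g2 = 0
    for i in members:
        if records[i].group is GroupLabel.GROUP1:
            g1 += records[i].count
        else:
            g2 += records[i].count
    return g1, g2


def _make_cluster(
    members: Sequence[int], records: Sequence[SeqRecord], centroid: Optional[int] = None
) -> Cluster:
    g1, g2 = _group_tallies(members, records)
    return Cluster(members=tuple(sorted(members)), g1=g1, g2=g2, centroid=centroid)


def agglomerative_merge_tree(matrix: IdentityMatrix, linkage: str) -> MergeTree:
    """Greedy agglomeration of the full identity matrix.

    Repeatedly merges the cluster pair with the highest linkage identity
    (min linkage: highest cross-pair identity; max: lowest; avg:
    unweighted mean over all cross pairs) until one cluster remains,
    recording the linkage identity of each merge. Ties resolve to the
    lexicographically smallest pair of minimum member indices.
    """
    if linkage not in _agglo.LINKAGES:
        raise ValueError(f"linkage must be one of {_agglo.LINKAGES}")
    merges, _ = _agglo.agglomerate(matrix.values, linkage)
    return MergeTree(n_leaves=len(matrix.ids), linkage=linkage, merges=tuple(merges))


def cut_at(
    tree: MergeTree, cutoff: float, records: Optional[Sequence[SeqRecord]] = None
) -> RingPartition:
    """Partition at one cutoff: apply merges with identity >= cutoff.

    A merge at exactly the cutoff applies (a sequence joins when its
    identity *meets* the threshold). Without ``records`` the group
    tallies are left at zero (geometry-only partitions for tests).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    parent = list(range(tree.n_leaves))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in tree.merges:
        if step.identity >= cutoff - CUTOFF_EPS:
            ra, rb = find(step.a[0]), find(step.b[0])
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(tree.n_leaves):
        groups.setdefault(find(i), []).append(i)
    member_lists = sorted(groups.values(), key=min)
    if records is None:
        clusters = tuple(
            Cluster(members=tuple(sorted(m)), g1=0, g2=0) for m in member_lists
        )
    else:
        clusters = tuple(_make_cluster(m, records) for m in member_lists)
    return RingPartition(cutoff=cutoff, clusters=clusters)


def _derive_parents(ladder: ClusterLadder) -> None:
    """Fill parent links by subset containment (agglomerative ladders)."""
    ladder.parent_of = [[None] * len(ladder.rings[0].clusters)]
    for level in range(1, len(ladder.rings)):
        prev_of: dict[int, int] = {}
        for k, cl in enumerate(ladder.rings[level - 1].clusters):
            for m in cl.members:
                prev_of[m] = k
        parents: list[Optional[int]] = []
        for cl in ladder.rings[level].clusters:
            owners = {prev_of[m] for m in cl.members}
            if len(owners) != 1:
                raise AssertionError(
                    f"refinement violated at cutoff {ladder.cutoffs[level]}: "
                    f"cluster {cl.members[:5]}... spans {len(owners)} parents"
                )
            parents.append(owners.pop())
        ladder.parent_of.append(parents)


def _check_ladder(ladder: ClusterLadder, n: int) -> None:
    """Assert partition, refinement, and cluster-count monotonicity."""
    prev_count = 0
    for ring in ladder.rings:
        seen: set[int] = set()
        for cl in ring.clusters:
            if seen & set(cl.members):
                raise AssertionError(f"overlapping clusters at cutoff {ring.cutoff}")
            seen.update(cl.members)
        if seen != set(range(n)):
            raise AssertionError(f"partition not exhaustive at cutoff {ring.cutoff}")
        if len(ring.clusters) < prev_count:
            raise AssertionError("cluster count decreased with increasing cutoff")
        prev_count = len(ring.clusters)


def build_agglomerative_ladder(
    records: Sequence[SeqRecord],
    linkage: str,
    cutoffs: Optional[Sequence[float]] = None,
    matrix: Optional[IdentityMatrix] = None,
) -> ClusterLadder:
    """Cut one merge tree at every cutoff of the ladder.

    Linkage monotonicity guarantees that the per-cutoff partitions nest,
    so parent links can be derived by containment.
    """
    cutoffs = default_cutoffs() if cutoffs is None else tuple(cutoffs)
    if matrix is None:
        matrix = identity_matrix(records)
    tree = agglomerative_merge_tree(matrix, linkage)
    rings = [cut_at(tree, c, records) for c in cutoffs]
    ladder = ClusterLadder(method=linkage, cutoffs=cutoffs, rings=rings)
    _derive_parents(ladder)
    _check_ladder(ladder, len(records))
    return ladder


class _IdentityLookup:
    """Identity queries record-vs-candidates without a full matrix."""

    def __init__(self, records: Sequence[SeqRecord], matrix: Optional[IdentityMatrix]):
        self.records = records
        self.values = matrix.values if matrix is not None else None
        lengths = {len(r.bases) for r in records}
        self.codes = (
            _codec.encode_many([r.bases for r in records])
            if len(lengths) == 1 and self.values is None
            else None
        )

    def against(self, i: int, candidates: Sequence[int]) -> np.ndarray:
        if self.values is not None:
            return self.values[i, list(candidates)]
        if self.codes is not None:
            return (self.codes[list(candidates)] == self.codes[i]).mean(axis=1)
        return np.array(
            [
                pairwise_identity(self.records[i].bases, self.records[c].bases)
                for c in candidates
            ]
        )


def greedy_centroid_partition(
    records: Sequence[SeqRecord],
    cutoff: float,
    order: Optional[Sequence[int]] = None,
    _lookup: Optional[_IdentityLookup] = None,
) -> RingPartition:
    """Greedy centroid clustering of records in a given processing order.

    The first record founds cluster 1 and becomes its centroid; each
    later record joins the centroid of highest identity if that identity
    meets the cutoff, else founds a new cluster. Ties between equally
    good centroids go to the earliest-founded cluster. ``order`` is the
    processing order as record indices (callers normally pass the
    staggered guide order); clusters in the returned partition are
    sorted by smallest member index.
    """
    if not records:
        raise ValueError("greedy_centroid_partition: no records")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    order = list(range(len(records))) if order is None else list(order)
    lookup = _IdentityLookup(records, None) if _lookup is None else _lookup
    centroids: list[int] = []
    membership: list[list[int]] = []
    for i in order:
        if centroids:
            idents = lookup.against(i, centroids)
            best = int(np.argmax(idents))  # first max = earliest-founded
            if idents[best] >= cutoff - CUTOFF_EPS:
                membership[best].append(i)
                continue
        centroids.append(i)
        membership.append([i])
    pairs = sorted(zip(membership, centroids), key=lambda mc: min(mc[0]))
    clusters = tuple(_make_cluster(m, records, centroid=c) for m, c in pairs)
    return RingPartition(cutoff=cutoff, clusters=clusters)


def build_divisive_ladder(
    records: Sequence[SeqRecord],
    cutoffs: Optional[Sequence[float]] = None,
    order: Optional[Sequence[int]] = None,
    matrix: Optional[IdentityMatrix] = None,
) -> ClusterLadder:
    """Stepwise top-down ladder via greedy centroid refinement.

    Level 0 partitions all records at the lowest cutoff in the staggered
    guide order; every subsequent level independently re-partitions each
    cluster of the previous level at the next cutoff, using the full
    staggered order restricted to the cluster's members. Refinement holds
    by construction and parent links are recorded directly.
    """
    if not records:
        raise ValueError("build_divisive_ladder: no records")
    cutoffs = default_cutoffs() if cutoffs is None else tuple(cutoffs)
    if order is None:
        if matrix is None and len(records) > 1:
            matrix = identity_matrix(records)
        order = guide_order(matrix) if len(records) > 1 else [0]
    staggered = staggered_order(order)
    rank_in_staggered = {idx: pos for pos, idx in enumerate(staggered)}
    lookup = _IdentityLookup(records, matrix)

    ring0 = greedy_centroid_partition(records, cutoffs[0], staggered, _lookup=lookup)
    rings = [ring0]
    parent_of: list[list[Optional[int]]] = [[None] * len(ring0.clusters)]
    for cutoff in cutoffs[1:]:
        new_clusters: list[Cluster] = []
        parents: list[int] = []
        for p_idx, parent in enumerate(rings[-1].clusters):
            sub_order = sorted(parent.members, key=rank_in_staggered.__getitem__)
            part = greedy_centroid_partition(records, cutoff, sub_order, _lookup=lookup)
            kept = [c for c in part.clusters if c.members]
            new_clusters.extend(kept)
            parents.extend([p_idx] * len(kept))
        sort_key = sorted(range(len(new_clusters)), key=lambda k: new_clusters[k].members[0])
        rings.append(
            RingPartition(cutoff=cutoff, clusters=tuple(new_clusters[k] for k in sort_key))
        )
        parent_of.append([parents[k] for k in sort_key])
    ladder = ClusterLadder(
        method="centroid", cutoffs=cutoffs, rings=rings, parent_of=parent_of
    )
    _check_ladder(ladder, len(records))
    return ladder


def write_ladder(
    ladder: ClusterLadder, records: Sequence[SeqRecord], path: str | Path
) -> None:
    """Export a ladder as TSV.

    Columns: cutoff, cluster_id, parent_cluster_id (``-`` at level 0),
    comma-separated member ids, g1, g2. Cluster ids are ``L<level>C<k>``.
    """
    with open(path, "w") as fh:
        fh.write(f"#method\t{ladder.method}\n")
        fh.write("cutoff\tcluster_id\tparent_cluster_id\tmember_ids\tg1\tg2\n")
        for level, ring in enumerate(ladder.rings):
            for k, cl in enumerate(ring.clusters):
                parent = ladder.parent_of[level][k]
                pid = "-" if parent is None else f"L{level - 1}C{parent}"
                ids = ",".join(records[m].id for m in cl.members)
                fh.write(
                    f"{ring.cutoff}\tL{level}C{k}\t{pid}\t{ids}\t{cl.g1}\t{cl.g2}\n"
                )


def read_ladder(path: str | Path, id_to_index: dict[str, int]) -> ClusterLadder:
    """Read a ladder TSV back (centroids are not serialised)."""
    method = "unknown"
    levels: dict[float, list[tuple[int, list[int], Optional[int], int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#method"):
                method = line.split("\t")[1]
                continue
            if line.startswith("cutoff\t"):
                continue
            cutoff_s, cid, pid, ids, g1, g2 = line.split("\t")
            cutoff = float(cutoff_s)
            level, k = (int(x) for x in cid[1:].split("C"))
            parent = None if pid == "-" else int(pid.split("C")[1])
            members = [id_to_index[i] for i in ids.split(",")]
            levels.setdefault(cutoff, []).append((k, members, parent, int(g1), int(g2)))
    cutoffs = tuple(sorted(levels))
    rings, parent_of = [], []
    for c in cutoffs:
        rows = sorted(levels[c])
        rings.append(
            RingPartition(
                cutoff=c,
                clusters=tuple(
                    Cluster(members=tuple(sorted(m)), g1=g1, g2=g2)
                    for _, m, _, g1, g2 in rows
                ),
            )
        )
        parent_of.append([p for _, _, p, _, _ in rows])
    return ClusterLadder(method=method, cutoffs=cutoffs, rings=rings, parent_of=parent_of)
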
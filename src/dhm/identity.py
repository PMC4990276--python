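"""Pairwise fractional identity and deterministic sequence ordering.

Fractional identity is the proportion of matching positions between two
sequences, in [0, 1] — the unit in which all clustering cutoffs are
expressed. Equal-length sequences are compared position by position;
unequal lengths fall back to a global end-to-end alignment (match +1,
mismatch -1, gap -2, no end-gap discount) and identity is matching
columns over alignment columns.

The *guide order* is the leaf order of an average-linkage (UPGMA)
hierarchy on 1 - identity, built with deterministic tie-breaking. It
arranges sequences so that neighbours in the order are high-identity
neighbourhoods, and it anchors the radial arrangement of every heat-map
ring. The *staggered order* alternates between the two ends of the guide
order so that the most mutually distant sequences are processed first —
they seed the centroids in greedy top-down clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _agglo, _codec
from .seqio import SeqRecord

__all__ = [
    "IdentityMatrix",
    "pairwise_identity",
    "identity_matrix",
    "guide_order",
    "staggered_order",
    "write_identity_matrix",
    "write_guide_order",
]

_MATCH, _MISMATCH, _GAP = 1.0, -1.0, -2.0


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric matrix of pairwise fractional identities in [0, 1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("self-identity must be 1")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("identities must lie in [0, 1]")


def _align_identity(a: str, b: str) -> float:
    """Global Needleman-Wunsch identity for unequal-length sequences.

    Traceback ties prefer the diagonal, then the vertical (gap in b) move,
    making the alignment — and hence the identity — deterministic.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * _GAP
    score[0, :] = np.arange(m + 1) * _GAP
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(ca[i - 1] == cb, _MATCH, _MISMATCH)
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + sub[j - 1], prev[j] + _GAP, row[j - 1] + _GAP)
    i, j, matches, columns = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (_MATCH if a[i - 1] == b[j - 1] else _MISMATCH)
            if score[i, j] == diag:
                matches += a[i - 1] == b[j - 1]
                i, j, columns = i - 1, j - 1, columns + 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + _GAP:
            i, columns = i - 1, columns + 1
            continue
        j, columns = j - 1, columns + 1
    return matches / columns


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two sequences.

    Equal lengths: matching positions / length. Unequal lengths: matching
    columns / alignment columns of a fixed-score global alignment.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return matches / len(a)
    return _align_identity(a, b)


def identity_matrix(records: Sequence[SeqRecord]) -> IdentityMatrix:
    """All-pairs fractional identities (vectorised for equal lengths)."""
    if not records:
        raise ValueError("identity_matrix: need at least one record")
    ids = tuple(r.id for r in records)
    n = len(records)
    lengths = {len(r.bases) for r in records}
    if len(lengths) == 1:
        codes = _codec.encode_many([r.bases for r in records])
        length = codes.shape[1]
        # matches(i,j) = sum_b <rows i and j both equal base b>
        matches = np.zeros((n, n), dtype=np.float64)
        for base in range(4):
            hit = (codes == base).astype(np.float32)
            matches += hit @ hit.T
        values = matches / length
        np.fill_diagonal(values, 1.0)
        np.clip(values, 0.0, 1.0, out=values)
    else:
        values = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = pairwise_identity(
                    records[i].bases, records[j].bases
                )
    return IdentityMatrix(ids=ids, values=values)


def guide_order(matrix: IdentityMatrix) -> list[int]:
    """Average-linkage (UPGMA) leaf order with deterministic tie-breaks.

    Pairs with the highest identity merge first; ties resolve to the
    lexicographically smallest pair of smallest member indices, and each
    internal node places the child containing the smallest original index
    first. All off-diagonal identities equal therefore yields the input
    order unchanged.
    """
    _, order = _agglo.agglomerate(matrix.values, "avg")
    return order


def staggered_order(order: Sequence[int]) -> list[int]:
    """Alternate the two ends of an ordering: first, last, second, ...

    Applied to a guide order this lists the most distantly related —
    and hence potentially cluster-splitting — sequences first, the
    seeding that greedy centroid clustering needs. For odd lengths the
    middle element comes last.
    """
    out = []
    lo, hi = 0, len(order) - 1
    while lo < hi:
        out.append(order[lo])
        out.append(order[hi])
        lo, hi = lo + 1, hi - 1
    if lo == hi:
        out.append(order[lo])
    return out


def write_identity_matrix(matrix: IdentityMatrix, path: str | Path) -> None:
    """Dump the matrix as TSV: id header row, then one row per sequence."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.ids) + "\n")
        for i, rid in enumerate(matrix.ids):
            row = "\t".join(f"{v:.6f}" for v in matrix.values[i])
            fh.write(f"{rid}\t{row}\n")


def write_guide_order(
    order: Sequence[int], ids: Sequence[str], path: str | Path
) -> None:
    """Export a guide order as one sequence id per line."""
    with open(path, "w") as fh:
        for idx in order:
            fh.write(ids[idx] + "\n")
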
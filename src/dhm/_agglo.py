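"""Shared agglomerative engine over a similarity (identity) matrix.

Single place implementing greedy pair merging with deterministic
tie-breaking, used both for min/max/avg-linkage merge trees and for the
average-linkage guide ordering. Linkage identities between clusters are
maintained with Lance-Williams style updates:

* ``min`` linkage (single): similarity of two clusters is their *highest*
  cross-pair identity — one agreeing edge suffices to join.
* ``max`` linkage (complete): the *lowest* cross-pair identity — every
  edge must agree.
* ``avg`` linkage (UPGMA): the unweighted arithmetic mean over all cross
  pairs (the size-weighted recurrence reproduces it exactly).

At every step the pair with the highest linkage identity is merged; ties
are broken toward the lexicographically smallest pair of smallest member
indices, and within a merged node the child containing the smallest
original index is placed first, so leaf orders and merge sequences are
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LINKAGES = ("min", "max", "avg")


@dataclass(frozen=True)
class MergeStep:
    """One merge: ordered member tuples of the two clusters and the
    linkage identity at which they joined."""

    a: tuple[int, ...]
    b: tuple[int, ...]
    identity: float


def agglomerate(
    values: np.ndarray, linkage: str
) -> tuple[list[MergeStep], list[int]]:
    """Greedy agglomeration of an n x n identity matrix.

    Returns the n-1 merge steps (in merge order) and the final leaf
    order of the single remaining cluster.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    n = values.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    if n == 1:
        return [], [0]

    sim = np.array(values, dtype=np.float64)
    np.fill_diagonal(sim, -np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.float64)
    members: list[list[int] | None] = [[i] for i in range(n)]
    minmember = np.arange(n)
    merges: list[MergeStep] = []

    for _ in range(n - 1):
        row_max = sim.max(axis=1)
        best = row_max.max()
        # tie-break: among all pairs at the best identity, the winning pair
        # contains the participant with the smallest original index, paired
        # with its smallest-indexed partner at that identity
        cand_rows = np.where(row_max == best)[0]
        i = cand_rows[np.argmin(minmember[cand_rows])]
        cand_cols = np.where(sim[i] == best)[0]
        j = cand_cols[np.argmin(minmember[cand_cols])]

        mi, mj = members[i], members[j]
        assert mi is not None and mj is not None
        if minmember[i] <= minmember[j]:
            a, b, merged = mi, mj, mi + mj
        else:
            a, b, merged = mj, mi, mj + mi
        merges.append(MergeStep(tuple(a), tuple(b), float(best)))

        # keep index i, retire index j
        if linkage == "min":
            new_row = np.maximum(sim[i], sim[j])
        elif linkage == "max":
            new_row = np.minimum(sim[i], sim[j])
        else:
            new_row = (sizes[i] * sim[i] + sizes[j] * sim[j]) / (sizes[i] + sizes[j])
        sim[i, :] = new_row
        sim[:, i] = new_row
        sim[i, i] = -np.inf
        sim[j, :] = -np.inf
        sim[:, j] = -np.inf
        sizes[i] += sizes[j]
        active[j] = False
        members[i] = merged
        members[j] = None
        minmember[i] = min(minmember[i], minmember[j])

    final = members[int(np.where(active)[0][0])]
    assert final is not None
    return merges, final
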
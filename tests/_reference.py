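"""Independent naive oracles for clustering behaviour.

These deliberately avoid the package's merge-tree/cut machinery: each
per-cutoff partition is grown by recomputing cluster-pair linkage from
the raw pairwise identities at every step, and the greedy centroid rule
is re-simulated literally from its textual definition. Slow (O(n^3) and
worse) but obviously correct on small inputs.
"""

from __future__ import annotations

from itertools import product

EPS = 1e-9


def _linkage_value(a: list[int], b: list[int], ident, linkage: str) -> float:
    vals = [ident[i][j] for i, j in product(a, b)]
    if linkage == "min":  # single linkage: one agreeing edge suffices
        return max(vals)
    if linkage == "max":  # complete linkage: every edge must agree
        return min(vals)
    return sum(vals) / len(vals)


def naive_linkage_partition(ident, linkage: str, cutoff: float) -> set[frozenset[int]]:
    """Independent per-cutoff agglomerative run.

    Starting from singletons, repeatedly merge the cluster pair with the
    highest linkage identity while that identity meets the cutoff; ties
    go to the lexicographically smallest pair of minimum member indices.
    """
    n = len(ident)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                v = _linkage_value(clusters[x], clusters[y], ident, linkage)
                key = (-v, min(clusters[x] + clusters[y]),
                       max(min(clusters[x]), min(clusters[y])))
                if best is None or key < best[0]:
                    best = (key, x, y, v)
        _, x, y, v = best
        if v < cutoff - EPS:
            break
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return {frozenset(c) for c in clusters}


def naive_greedy_partition(ident, order: list[int], cutoff: float):
    """Literal re-simulation of the greedy centroid rule.

    Each sequence, in order, joins the existing centroid with the best
    identity at or above the cutoff (earliest centroid wins ties), or
    founds a new cluster as its centroid.
    """
    centroids: list[int] = []
    members: list[list[int]] = []
    for i in order:
        best_k, best_v = None, None
        for k, c in enumerate(centroids):
            v = ident[i][c]
            if best_v is None or v > best_v + EPS:
                best_k, best_v = k, v
        if best_v is not None and best_v >= cutoff - EPS:
            members[best_k].append(i)
        else:
            centroids.append(i)
            members.append([i])
    return {frozenset(m) for m in members}, list(centroids)
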
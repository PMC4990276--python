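"""Simulators for the two artificial datasets used to demonstrate DHMs.

Two simplified evolutionary processes produce diverging DNA populations:

* **Mutation lineage** — a fixed-size set of sequences (default 100 x
  100 bp), all identical at iteration 0 with exactly 50% GC content; at
  each iteration every sequence independently receives one random base
  substitution. After 15 iterations every sequence carries 15 events.

* **Population growth** — a single ancestor is repeatedly duplicated:
  each generation every sequence yields one unchanged copy and one copy
  with a single random substitution, so generation g holds 2^g sequences.

Substitutions pick a position uniformly at random and replace the base
with one of the three other bases, uniformly; the same position may be
hit more than once, so reversions can occur.

Both simulators enforce a *group-evening* constraint via rejection
sampling: the GROUP1 / GROUP2 (GC <= 50% / > 50%) counts of a returned
run must be within a bound (absolute +-20 sequences for the lineage set,
a fraction 0.05 of the total for the growth set); runs that violate the
bound are discarded and regenerated from the next derived seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import _codec
from .seqio import GroupLabel, SeqRecord, assign_group, write_fasta

__all__ = [
    "EveningMode",
    "CheckAt",
    "EveningPolicy",
    "GroupEveningError",
    "GenerationSet",
    "EndpointSpec",
    "check_evening",
    "make_ancestor",
    "substitute_once",
    "simulate_mutation_lineage",
    "simulate_population_growth",
    "endpoint_count",
    "write_generation_set",
    "DEFAULT_LINEAGE_POLICY",
    "DEFAULT_GROWTH_POLICY",
]


class EveningMode(enum.Enum):
    ABSOLUTE = "absolute"  # bound on |n1 - n2| in sequences
    FRACTIONAL = "fractional"  # bound on |n1 - n2| / total


class CheckAt(enum.Enum):
    FINAL_ONLY = "final"
    EVERY_SNAPSHOT = "every"  # snapshots 1..T (snapshot 0 is degenerate)
    NONE = "none"


@dataclass(frozen=True)
class EveningPolicy:
    """Group-evening constraint enforced by restart-based rejection sampling.

    ``threshold`` is a sequence count for ABSOLUTE mode and a fraction of
    the total for FRACTIONAL mode. A difference exactly equal to the bound
    passes; only strictly exceeding it triggers a restart. ``check_at``
    selects which snapshots are checked (EVERY_SNAPSHOT skips snapshot 0,
    which for the lineage set always has all sequences in GROUP1).
    """

    mode: EveningMode
    threshold: float
    check_at: CheckAt = CheckAt.FINAL_ONLY
    max_restarts: int = 1000

    def __post_init__(self) -> None:
        if self.mode is EveningMode.ABSOLUTE:
            if self.threshold < 1 or self.threshold != int(self.threshold):
                raise ValueError("ABSOLUTE threshold must be an integer >= 1")
        else:
            if not 0 < self.threshold < 1:
                raise ValueError("FRACTIONAL threshold must be in (0, 1)")
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")


DEFAULT_LINEAGE_POLICY = EveningPolicy(EveningMode.ABSOLUTE, 20)
DEFAULT_GROWTH_POLICY = EveningPolicy(EveningMode.FRACTIONAL, 0.05)


class GroupEveningError(RuntimeError):
    """Raised when no run satisfying the evening policy was found."""

    def __init__(self, attempts: int, last_imbalance: int, total: int):
        self.attempts = attempts
        self.last_imbalance = last_imbalance
        super().__init__(
            f"group evening failed after {attempts} attempts "
            f"(last |Group1-Group2| = {last_imbalance} of {total} sequences)"
        )


def check_evening(count1: int, count2: int, policy: EveningPolicy) -> bool:
    """True iff the group counts satisfy the policy bound (equality passes)."""
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    diff = abs(count1 - count2)
    if policy.mode is EveningMode.ABSOLUTE:
        return diff <= policy.threshold
    return diff <= policy.threshold * (count1 + count2)


@dataclass
class GenerationSet:
    """Ordered snapshots of a simulation run.

    ``snapshots[m]`` is the record collection at iteration/generation m;
    the lineage simulator keeps a constant population, the growth
    simulator doubles it each generation.
    """

    snapshots: list[list[SeqRecord]]
    ancestor: SeqRecord
    seed: int
    restarts_used: int
    policy: EveningPolicy = field(default=DEFAULT_LINEAGE_POLICY)

    def group_counts(self, index: int) -> tuple[int, int]:
        """(GROUP1, GROUP2) abundance totals at snapshot ``index``."""
        g1 = sum(r.count for r in self.snapshots[index] if r.group is GroupLabel.GROUP1)
        g2 = sum(r.count for r in self.snapshots[index] if r.group is GroupLabel.GROUP2)
        return g1, g2


@dataclass(frozen=True)
class EndpointSpec:
    """Size of the theoretical endpoint cluster distribution.

    With ``b`` possible bases and ``n`` positions, unbounded mutation can
    reach exactly ``b**n`` distinct sequences — the limiting cluster
    distribution in which every possible sequence exists.
    """

    b: int
    n: int

    def __post_init__(self) -> None:
        if self.b < 2 or self.n < 1:
            raise ValueError("need b >= 2 and n >= 1")


def endpoint_count(spec: EndpointSpec) -> int:
    """Exact number of distinct length-n sequences over b bases (b**n)."""
    return spec.b ** spec.n


def make_ancestor(
    length: int,
    gc_exact: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    rec_id: str = "ancestor",
) -> SeqRecord:
    """Random ancestral sequence, optionally with an exact GC count.

    With ``gc_exact`` given, exactly ``gc_exact * length`` positions (which
    must be integral) hold G or C; the arrangement and the choice within
    {G,C} / {A,T} are uniform. Without it, bases are i.i.d. uniform.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if gc_exact is None:
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    else:
        k = gc_exact * length
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"gc_exact * length = {k} is not an integer")
        k = int(round(k))
        codes = np.empty(length, dtype=np.uint8)
        gc_positions = rng.choice(length, size=k, replace=False)
        is_gc = np.zeros(length, dtype=bool)
        is_gc[gc_positions] = True
        # G/C are codes 1,2; A/T are codes 0,3
        codes[is_gc] = rng.integers(1, 3, size=k, dtype=np.uint8)
        codes[~is_gc] = rng.integers(0, 2, size=length - k, dtype=np.uint8) * 3
    bases = _codec.decode(codes)
    return SeqRecord(id=rec_id, bases=bases, group=assign_group(bases))


def substitute_once(bases: str, rng: np.random.Generator) -> str:
    """Apply one random substitution: uniform position, uniform new base.

    The output differs from the input at exactly one position; repeated
    calls may hit the same position and revert earlier changes.
    """
    if not bases:
        raise ValueError("substitute_once: empty sequence")
    codes = _codec.encode(bases)
    pos = int(rng.integers(len(codes)))
    offset = int(rng.integers(1, 4))
    codes[pos] = (codes[pos] + offset) % 4
    return _codec.decode(codes)


def _mutate_rows(pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One substitution per row of a code matrix (vectorised substitute_once)."""
    n, length = pop.shape
    out = pop.copy()
    pos = rng.integers(0, length, size=n)
    offset = rng.integers(1, 4, size=n, dtype=np.uint8)
    rows = np.arange(n)
    out[rows, pos] = (out[rows, pos] + offset) % 4
    return out


def _checked_indices(n_snapshots: int, policy: EveningPolicy) -> list[int]:
    if policy.check_at is CheckAt.NONE:
        return []
    if policy.check_at is CheckAt.FINAL_ONLY:
        return [n_snapshots - 1]
    return list(range(1, n_snapshots))


def _passes(pops: list[np.ndarray], policy: EveningPolicy) -> tuple[bool, int, int]:
    """Check the evening policy; returns (ok, worst imbalance, its total)."""
    worst, worst_total, ok = 0, 0, True
    for idx in _checked_indices(len(pops), policy):
        gc = _codec.gc_counts(pops[idx])
        length = pops[idx].shape[1]
        n1 = int((2 * gc <= length).sum())
        n2 = pops[idx].shape[0] - n1
        if not check_evening(n1, n2, policy):
            ok = False
        if abs(n1 - n2) >= worst:
            worst, worst_total = abs(n1 - n2), n1 + n2
    return ok, worst, worst_total


def _materialise(
    pops: list[np.ndarray], events: list[np.ndarray], prefix: str
) -> list[list[SeqRecord]]:
    snapshots = []
    for m, pop in enumerate(pops):
        seqs = _codec.decode_many(pop)
        gc = _codec.gc_counts(pop)
        length = pop.shape[1]
        recs = [
            SeqRecord(
                id=f"{prefix}{m}_{i}",
                bases=seqs[i],
                group=GroupLabel.GROUP1 if 2 * gc[i] <= length else GroupLabel.GROUP2,
                events=int(events[m][i]),
            )
            for i in range(pop.shape[0])
        ]
        snapshots.append(recs)
    return snapshots


def simulate_mutation_lineage(
    n_seqs: int = 100,
    length: int = 100,
    iterations: int = 15,
    policy: Optional[EveningPolicy] = None,
    seed: int = 0,
) -> GenerationSet:
    """Constant-size population, one substitution per sequence per iteration.

    Snapshot 0 holds ``n_seqs`` identical copies of a 50%-GC ancestor;
    snapshot m+1 applies one independent substitution to every sequence of
    snapshot m, so every record at snapshot m carries exactly m events.
    Restart r reruns the whole process from ``seed + r``.
    """
    if n_seqs < 1 or length < 1 or iterations < 1:
        raise ValueError("n_seqs, length and iterations must be >= 1")
    policy = DEFAULT_LINEAGE_POLICY if policy is None else policy
    last_imb, last_total = 0, 0
    for restart in range(policy.max_restarts):
        rng = np.random.default_rng(seed + restart)
        ancestor = make_ancestor(length, gc_exact=0.5, rng=rng)
        pop = np.tile(_codec.encode(ancestor.bases), (n_seqs, 1))
        pops = [pop]
        for _ in range(iterations):
            pops.append(_mutate_rows(pops[-1], rng))
        ok, last_imb, last_total = _passes(pops, policy)
        if ok:
            events = [np.full(n_seqs, m) for m in range(iterations + 1)]
            return GenerationSet(
                snapshots=_materialise(pops, events, "m"),
                ancestor=ancestor,
                seed=seed,
                restarts_used=restart,
                policy=policy,
            )
    raise GroupEveningError(policy.max_restarts, last_imb, last_total)


def simulate_population_growth(
    length: int = 100,
    generations: int = 15,
    policy: Optional[EveningPolicy] = None,
    seed: int = 0,
    ancestor_gc: Optional[float] = 0.5,
) -> GenerationSet:
    """Mutate-and-duplicate growth: 2^g sequences at generation g.

    Each generation every sequence produces one unchanged copy and one
    copy with a single substitution (events incremented on the mutated
    copy only). The ancestor defaults to an exact 50%-GC composition
    (``ancestor_gc=None`` for fully random, as an unconstrained variant).
    """
    if length < 1 or generations < 1:
        raise ValueError("length and generations must be >= 1")
    policy = DEFAULT_GROWTH_POLICY if policy is None else policy
    last_imb, last_total = 0, 0
    for restart in range(policy.max_restarts):
        rng = np.random.default_rng(seed + restart)
        ancestor = make_ancestor(length, gc_exact=ancestor_gc, rng=rng)
        pops = [_codec.encode(ancestor.bases)[None, :]]
        events = [np.zeros(1, dtype=np.int64)]
        for _ in range(generations):
            mutated = _mutate_rows(pops[-1], rng)
            pops.append(np.concatenate([pops[-1], mutated]))
            events.append(np.concatenate([events[-1], events[-1] + 1]))
        ok, last_imb, last_total = _passes(pops, policy)
        if ok:
            return GenerationSet(
                snapshots=_materialise(pops, events, "g"),
                ancestor=ancestor,
                seed=seed,
                restarts_used=restart,
                policy=policy,
            )
    raise GroupEveningError(policy.max_restarts, last_imb, last_total)


def write_generation_set(
    gs: GenerationSet, out_dir: str | Path, prefix: str = "snapshot"
) -> list[Path]:
    """Write one FASTA per snapshot plus a run manifest; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m, snap in enumerate(gs.snapshots):
        p = out_dir / f"{prefix}_{m}.fasta"
        write_fasta(snap, p)
        paths.append(p)
    manifest = out_dir / f"{prefix}_manifest.txt"
    with open(manifest, "w") as fh:
        fh.write(f"seed\t{gs.seed}\n")
        fh.write(f"restarts_used\t{gs.restarts_used}\n")
        fh.write(
            f"policy\t{gs.policy.mode.value}\t{gs.policy.threshold}\t"
            f"{gs.policy.check_at.value}\n"
        )
        fh.write("snapshot\tn_records\tgroup1\tgroup2\n")
        for m in range(len(gs.snapshots)):
            g1, g2 = gs.group_counts(m)
            fh.write(f"{m}\t{len(gs.snapshots[m])}\t{g1}\t{g2}\n")
    paths.append(manifest)
    return paths
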
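"""FASTA input/output, GC-content group assignment, and dereplication.

Sequences are plain ACGT DNA. Each record carries a phenotype group label:
by default GROUP1 for GC content <= 50% and GROUP2 for GC content > 50%,
evaluated in integer arithmetic so the boundary is exact. Group labels can
alternatively come from a two-column tab-separated id -> {1,2} table, so a
real phenotype can stand in for GC content.

Identical sequences can be collapsed into a single record whose ``count``
field records the abundance; clustering and heat-map colouring downstream
weight clusters by these counts.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GroupLabel",
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "gc_fraction",
    "assign_group",
    "dereplicate",
    "read_group_map",
    "apply_group_map",
]

_VALID = re.compile(r"[ACGT]+\Z")


class GroupLabel(enum.Enum):
    """Two-way phenotype label (GC-derived by default)."""

    GROUP1 = 1  # GC <= 50%
    GROUP2 = 2  # GC > 50%


@dataclass(frozen=True)
class SeqRecord:
    """One DNA sequence with its group label and abundance.

    ``count`` is the number of identical copies this record stands for
    (>= 1); ``events`` is the number of substitution events applied since
    the ancestor, populated by the simulators and 0 for external data.
    """

    id: str
    bases: str
    group: GroupLabel = field(default=GroupLabel.GROUP1)
    count: int = 1
    events: int = 0

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not _VALID.match(self.bases):
            pos = next(i for i, c in enumerate(self.bases) if c not in "ACGT")
            raise ValueError(
                f"record {self.id!r}: invalid character {self.bases[pos]!r} "
                f"at position {pos} (only A/C/G/T are accepted)"
            )
        if self.count < 1:
            raise ValueError(f"record {self.id!r}: count must be >= 1")
        if self.events < 0:
            raise ValueError(f"record {self.id!r}: events must be >= 0")

    def with_group(self, group: GroupLabel) -> "SeqRecord":
        return replace(self, group=group)


def gc_fraction(bases: str) -> float:
    """Fraction of G/C characters in ``bases``."""
    if not bases:
        raise ValueError("gc_fraction: empty sequence")
    if not _VALID.match(bases):
        raise ValueError("gc_fraction: sequence must contain only A/C/G/T")
    return (bases.count("G") + bases.count("C")) / len(bases)


def assign_group(bases: str) -> GroupLabel:
    """GROUP1 iff GC content <= 50%, else GROUP2.

    The boundary is decided as ``2 * gc_count <= length`` in integer
    arithmetic, so a sequence with exactly half G/C is GROUP1.
    """
    if not bases:
        raise ValueError("assign_group: empty sequence")
    if not _VALID.match(bases):
        raise ValueError("assign_group: sequence must contain only A/C/G/T")
    gc = bases.count("G") + bases.count("C")
    return GroupLabel.GROUP1 if 2 * gc <= len(bases) else GroupLabel.GROUP2


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into labelled records.

    The first whitespace-delimited token of each header becomes the record
    id; multi-line sequences are joined; lowercase bases are uppercased.
    Group labels are assigned from GC content (use :func:`apply_group_map`
    to override). Duplicate ids and non-ACGT characters (including
    ambiguity codes and gaps) are errors; an empty file yields an empty
    list.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        sr = SeqRecord(id=rec.id, bases=bases, group=GroupLabel.GROUP1)
        records.append(sr.with_group(assign_group(bases)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain wrapped FASTA (roundtrips with read_fasta)."""
    if width < 1:
        raise ValueError("write_fasta: width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def dereplicate(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Collapse identical sequences, summing abundances.

    One output record per distinct sequence string, keeping the id, group
    and events of its first occurrence, in first-occurrence order. Total
    abundance is conserved; the operation is idempotent.
    """
    by_seq: dict[str, SeqRecord] = {}
    for rec in records:
        prev = by_seq.get(rec.bases)
        if prev is None:
            by_seq[rec.bases] = rec
        else:
            by_seq[rec.bases] = replace(prev, count=prev.count + rec.count)
    return list(by_seq.values())


def read_group_map(path: str | Path) -> dict[str, GroupLabel]:
    """Read a two-column tab-separated ``<seq_id>\\t<1|2>`` group table."""
    mapping: dict[str, GroupLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("1", "2"):
                raise ValueError(
                    f"{path}:{lineno}: expected '<seq_id>\\t<1|2>', got {line!r}"
                )
            if parts[0] in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            mapping[parts[0]] = GroupLabel(int(parts[1]))
    return mapping


def apply_group_map(
    records: Sequence[SeqRecord], mapping: dict[str, GroupLabel]
) -> list[SeqRecord]:
    """Relabel records from an id -> group mapping (every id must be present)."""
    missing = [r.id for r in records if r.id not in mapping]
    if missing:
        raise ValueError(f"group map is missing ids: {missing[:5]!r}...")
    return [r.with_group(mapping[r.id]) for r in records]
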
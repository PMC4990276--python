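"""Internal numeric codec for ACGT strings (0=A, 1=C, 2=G, 3=T).

G/C are codes 1 and 2, so ``(code == 1) | (code == 2)`` counts GC content.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

BASES = "ACGT"
_LUT = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _LUT[ord(_c)] = _i


def encode(bases: str) -> np.ndarray:
    """Encode one ACGT string as a uint8 code vector."""
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = _LUT[raw]
    if (out == 255).any():
        raise ValueError("encode: sequence must contain only A/C/G/T")
    return out


def encode_many(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("encode_many: sequences must have equal length")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    out = _LUT[raw].reshape(len(seqs), length)
    if (out == 255).any():
        raise ValueError("encode_many: sequences must contain only A/C/G/T")
    return out


_REV = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code vector back to an ACGT string."""
    return _REV[codes].tobytes().decode("ascii")


def decode_many(codes: np.ndarray) -> list[str]:
    """Decode an (n, L) code matrix into n ACGT strings."""
    ascii_rows = _REV[codes]
    return [row.tobytes().decode("ascii") for row in ascii_rows]


def gc_counts(codes: np.ndarray) -> np.ndarray:
    """Per-row G+C counts of an (n, L) code matrix."""
    return ((codes == 1) | (codes == 2)).sum(axis=1)
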
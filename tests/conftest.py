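from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dhm.seqio import SeqRecord, assign_group

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_bases(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_records(
    n: int, length: int = 20, seed: int = 0, mutate_from_common: bool = False
) -> list[SeqRecord]:
    """Random records; optionally correlated (mutated copies of one seed
    sequence) so that clustering at 0.75..1.0 is non-trivial."""
    rng = random.Random(seed)
    records = []
    if mutate_from_common:
        base = random_bases(rng, length)
        for i in range(n):
            seq = list(base)
            for _ in range(rng.randint(0, max(1, length // 4))):
                pos = rng.randrange(length)
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            s = "".join(seq)
            records.append(SeqRecord(id=f"s{i}", bases=s, group=assign_group(s)))
    else:
        seen = set()
        i = 0
        while len(records) < n:
            s = random_bases(rng, length)
            if s in seen:
                continue
            seen.add(s)
            records.append(SeqRecord(id=f"s{i}", bases=s, group=assign_group(s)))
            i += 1
    return records


def hamming_identity_matrix(records) -> list[list[float]]:
    """Plain-python pairwise identities, independent of dhm.identity."""
    n = len(records)
    out = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].bases, records[j].bases
            ident = sum(x == y for x, y in zip(a, b)) / len(a)
            out[i][j] = out[j][i] = ident
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
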
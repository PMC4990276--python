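import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dhm.identity import (
    IdentityMatrix,
    guide_order,
    identity_matrix,
    pairwise_identity,
    staggered_order,
    write_guide_order,
    write_identity_matrix,
)
from dhm.seqio import SeqRecord

from conftest import make_records

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)

MATCH, MISMATCH, GAP = 1, -1, -2


def brute_force_alignments(a: str, b: str):
    """Enumerate all global alignments of tiny strings with their scores
    and identities (matching columns / total columns)."""
    results = []

    def rec(i, j, score, matches, columns):
        if i == len(a) and j == len(b):
            results.append((score, matches / columns if columns else 1.0))
            return
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            rec(i + 1, j + 1, score + s, matches + (a[i] == b[j]), columns + 1)
        if i < len(a):
            rec(i + 1, j, score + GAP, matches, columns + 1)
        if j < len(b):
            rec(i, j + 1, score + GAP, matches, columns + 1)

    rec(0, 0, 0, 0, 0)
    return results


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("A" * 100, "A" * 100, 1.0),
            ("A" * 75 + "C" * 25, "A" * 75 + "G" * 25, 0.75),
            ("ACGT", "ACGA", 0.75),
        ],
    )
    def test_equal_length(self, a, b, expected):
        assert pairwise_identity(a, b) == expected

    @given(dna, dna)
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @given(dna)
    def test_self_identity(self, a):
        assert pairwise_identity(a, a) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_unequal_length_simple(self):
        # ACGT vs ACG: best global alignment is ACGT / ACG- -> 3/4
        assert pairwise_identity("ACGT", "ACG") == 0.75

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=5),
        st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    def test_unequal_matches_an_optimal_alignment(self, a, b):
        if len(a) == len(b):
            return
        options = brute_force_alignments(a, b)
        best = max(s for s, _ in options)
        optimal_idents = {
            round(ident, 12) for s, ident in options if s == best
        }
        assert round(pairwise_identity(a, b), 12) in optimal_idents

    def test_deterministic(self):
        vals = {pairwise_identity("ACGTACGT", "ACGAC") for _ in range(5)}
        assert len(vals) == 1


class TestIdentityMatrix:
    def test_single_record(self):
        m = identity_matrix([SeqRecord(id="a", bases="ACGT")])
        assert m.values.shape == (1, 1) and m.values[0, 0] == 1.0

    def test_symmetry_and_diagonal(self):
        recs = make_records(12, length=30, seed=4, mutate_from_common=True)
        m = identity_matrix(recs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_hamming_values(self):
        base = "A" * 100
        recs = [
            SeqRecord(id="a", bases=base),
            SeqRecord(id="b", bases="C" * 10 + "A" * 90),
            SeqRecord(id="c", bases="C" * 30 + "A" * 70),
        ]
        m = identity_matrix(recs)
        assert m.values[0, 1] == pytest.approx(0.9)
        assert m.values[0, 2] == pytest.approx(0.7)
        assert m.values[1, 2] == pytest.approx(0.8)

    def test_matches_scalar_routine(self):
        recs = make_records(8, length=25, seed=1, mutate_from_common=True)
        m = identity_matrix(recs)
        for i, j in itertools.combinations(range(len(recs)), 2):
            assert m.values[i, j] == pytest.approx(
                pairwise_identity(recs[i].bases, recs[j].bases)
            )

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            IdentityMatrix(ids=("a", "b"), values=bad)

    def test_tsv_dump(self, tmp_path):
        recs = make_records(4, length=10, seed=2)
        m = identity_matrix(recs)
        p = tmp_path / "m.tsv"
        write_identity_matrix(m, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 5 and lines[0].startswith("id\t")


class TestGuideOrder:
    def test_single_record(self):
        m = identity_matrix([SeqRecord(id="a", bases="ACGT")])
        assert guide_order(m) == [0]

    def test_close_pair_adjacent(self):
        # brute-force UPGMA on 3 leaves: A,B merge first, so adjacent
        values = np.array([[1.0, 0.9, 0.6], [0.9, 1.0, 0.6], [0.6, 0.6, 1.0]])
        order = guide_order(IdentityMatrix(ids=("A", "B", "C"), values=values))
        ab = {order.index(0), order.index(1)}
        assert max(ab) - min(ab) == 1

    def test_all_ties_preserve_input_order(self):
        values = np.full((5, 5), 0.5)
        np.fill_diagonal(values, 1.0)
        m = IdentityMatrix(ids=tuple("abcde"), values=values)
        assert guide_order(m) == [0, 1, 2, 3, 4]

    def test_is_permutation(self):
        recs = make_records(15, length=40, seed=6, mutate_from_common=True)
        order = guide_order(identity_matrix(recs))
        assert sorted(order) == list(range(15))

    def test_neighbours_are_similar(self):
        # adjacent positions should average higher identity than random pairs
        recs = make_records(30, length=60, seed=8, mutate_from_common=True)
        m = identity_matrix(recs)
        order = guide_order(m)
        adjacent = np.mean(
            [m.values[order[i], order[i + 1]] for i in range(len(order) - 1)]
        )
        assert adjacent >= m.values[np.triu_indices(30, 1)].mean()

    def test_export(self, tmp_path):
        p = tmp_path / "o.txt"
        write_guide_order([2, 0, 1], ["a", "b", "c"], p)
        assert p.read_text().splitlines() == ["c", "a", "b"]


class TestStaggeredOrder:
    @pytest.mark.parametrize(
        "order,expected",
        [
            (["a", "b", "c", "d", "e"], ["a", "e", "b", "d", "c"]),
            (["a", "b", "c", "d"], ["a", "d", "b", "c"]),
            (["a"], ["a"]),
        ],
    )
    def test_alternates_ends(self, order, expected):
        assert staggered_order(order) == expected

    @given(st.integers(min_value=1, max_value=200))
    def test_is_permutation(self, n):
        assert sorted(staggered_order(list(range(n)))) == list(range(n))
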
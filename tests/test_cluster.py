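import numpy as np
import pytest

from dhm.cluster import (
    agglomerative_merge_tree,
    build_agglomerative_ladder,
    build_divisive_ladder,
    cut_at,
    default_cutoffs,
    greedy_centroid_partition,
    read_ladder,
    write_ladder,
)
from dhm.identity import IdentityMatrix, guide_order, identity_matrix, staggered_order
from dhm.seqio import SeqRecord, assign_group

from conftest import hamming_identity_matrix, make_records
from _reference import naive_greedy_partition, naive_linkage_partition


def _abc_matrix() -> IdentityMatrix:
    # AB = 0.9, AC = 0.8, BC = 0.7
    values = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
    return IdentityMatrix(ids=("A", "B", "C"), values=values)


def partition_sets(ring):
    return {frozenset(c.members) for c in ring.clusters}


def is_refinement(fine, coarse) -> bool:
    """Every cluster of `fine` lies inside one cluster of `coarse`."""
    return all(any(f <= c for c in coarse) for f in fine)


class TestMergeTree:
    @pytest.mark.parametrize(
        "linkage,second_identity",
        [("min", 0.8), ("max", 0.7), ("avg", 0.75)],
    )
    def test_three_leaf_linkage_values(self, linkage, second_identity):
        tree = agglomerative_merge_tree(_abc_matrix(), linkage)
        assert len(tree.merges) == 2
        assert tree.merges[0].identity == pytest.approx(0.9)
        assert set(tree.merges[0].a + tree.merges[0].b) == {0, 1}
        assert tree.merges[1].identity == pytest.approx(second_identity)

    def test_monotone_linkage_identities(self):
        recs = make_records(20, length=40, seed=5, mutate_from_common=True)
        m = identity_matrix(recs)
        for linkage in ("min", "max", "avg"):
            tree = agglomerative_merge_tree(m, linkage)
            idents = [s.identity for s in tree.merges]
            assert all(a >= b - 1e-12 for a, b in zip(idents, idents[1:]))


class TestCutAt:
    def test_avg_boundary_merge_applies(self):
        tree = agglomerative_merge_tree(_abc_matrix(), "avg")
        ring = cut_at(tree, 0.75)  # merge at exactly 0.75 joins
        assert partition_sets(ring) == {frozenset({0, 1, 2})}

    def test_max_leaves_nonjoining_cluster(self):
        tree = agglomerative_merge_tree(_abc_matrix(), "max")
        ring = cut_at(tree, 0.75)
        assert partition_sets(ring) == {frozenset({0, 1}), frozenset({2})}

    def test_all_distinct_singletons_at_one(self):
        recs = make_records(10, length=30, seed=2)
        tree = agglomerative_merge_tree(identity_matrix(recs), "min")
        ring = cut_at(tree, 1.0)
        assert len(ring.clusters) == 10


class TestAgglomerativeLadder:
    def test_single_sequence(self):
        lad = build_agglomerative_ladder([SeqRecord(id="a", bases="ACGT")], "avg")
        assert all(len(r.clusters) == 1 for r in lad.rings)

    def test_identical_sequences_one_cluster_everywhere(self):
        recs = [SeqRecord(id=f"s{i}", bases="ACGT" * 10) for i in range(10)]
        for linkage in ("min", "max", "avg"):
            lad = build_agglomerative_ladder(recs, linkage)
            assert all(len(r.clusters) == 1 for r in lad.rings)

    def test_counts_nondecreasing_and_nested(self):
        recs = make_records(20, length=40, seed=7, mutate_from_common=True)
        for linkage in ("min", "max", "avg"):
            lad = build_agglomerative_ladder(recs, linkage)
            counts = [len(r.clusters) for r in lad.rings]
            assert counts == sorted(counts)
            for lv in range(1, len(lad.rings)):
                assert is_refinement(
                    lad.rings[lv].member_sets(), lad.rings[lv - 1].member_sets()
                )

    def test_group_tallies_conserved(self):
        recs = make_records(15, length=30, seed=9, mutate_from_common=True)
        lad = build_agglomerative_ladder(recs, "avg")
        total = sum(r.count for r in recs)
        for ring in lad.rings:
            assert sum(c.g1 + c.g2 for c in ring.clusters) == total


class TestGreedyCentroid:
    def test_hand_trace_split(self):
        recs = [
            SeqRecord(id="A", bases="A" * 20),
            SeqRecord(id="B", bases="A" * 18 + "C" * 2),  # AB = 0.9
            SeqRecord(id="C", bases="A" * 16 + "G" * 4),  # AC = 0.8, BC = 0.7
        ]
        ring = greedy_centroid_partition(recs, 0.85)
        assert partition_sets(ring) == {frozenset({0, 1}), frozenset({2})}
        assert {c.centroid for c in ring.clusters} == {0, 2}

    def test_hand_trace_single_cluster(self):
        recs = [
            SeqRecord(id="A", bases="A" * 20),
            SeqRecord(id="B", bases="A" * 18 + "C" * 2),
            SeqRecord(id="C", bases="A" * 16 + "G" * 4),
        ]
        ring = greedy_centroid_partition(recs, 0.75)
        assert partition_sets(ring) == {frozenset({0, 1, 2})}
        assert ring.clusters[0].centroid == 0

    def test_first_record_is_centroid_when_all_close(self):
        recs = make_records(8, length=40, seed=3, mutate_from_common=True)
        ring = greedy_centroid_partition(recs, 0.01)
        assert len(ring.clusters) == 1
        assert ring.clusters[0].centroid == 0


class TestDivisiveLadder:
    def test_single_sequence(self):
        lad = build_divisive_ladder([SeqRecord(id="a", bases="ACGT")])
        assert len(lad.rings) == 26
        assert all(len(r.clusters) == 1 for r in lad.rings)

    def test_identical_sequences_never_split(self):
        recs = [SeqRecord(id=f"s{i}", bases="ACGT" * 5) for i in range(6)]
        lad = build_divisive_ladder(recs)
        assert all(len(r.clusters) == 1 for r in lad.rings)

    def test_refinement_and_parent_links(self):
        recs = make_records(50, length=60, seed=11, mutate_from_common=True)
        lad = build_divisive_ladder(recs)
        for lv in range(1, len(lad.rings)):
            prev_sets = lad.rings[lv - 1].member_sets()
            for k, cl in enumerate(lad.rings[lv].clusters):
                parent = lad.parent_of[lv][k]
                assert set(cl.members) <= prev_sets[parent]

    def test_centroid_is_member(self):
        recs = make_records(30, length=40, seed=13, mutate_from_common=True)
        lad = build_divisive_ladder(recs)
        for ring in lad.rings:
            for cl in ring.clusters:
                assert cl.centroid in cl.members


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_agglomerative_matches_naive(self, seed):
        recs = make_records(8, length=16, seed=seed, mutate_from_common=True)
        ident = hamming_identity_matrix(recs)
        m = identity_matrix(recs)
        for linkage in ("min", "max", "avg"):
            lad = build_agglomerative_ladder(recs, linkage, matrix=m)
            for ring in lad.rings:
                expected = naive_linkage_partition(ident, linkage, ring.cutoff)
                assert partition_sets(ring) == expected, (linkage, ring.cutoff)

    @pytest.mark.parametrize("seed", range(12))
    def test_greedy_matches_naive(self, seed):
        recs = make_records(9, length=16, seed=seed, mutate_from_common=True)
        ident = hamming_identity_matrix(recs)
        order = staggered_order(guide_order(identity_matrix(recs)))
        for cutoff in (0.75, 0.8, 0.9, 0.95, 1.0):
            ring = greedy_centroid_partition(recs, cutoff, order)
            expected, centroids = naive_greedy_partition(ident, order, cutoff)
            assert partition_sets(ring) == expected
            assert {c.centroid for c in ring.clusters} == set(centroids)


class TestCoarsenessOrdering:
    def test_min_linkage_is_coarsest(self):
        """Single linkage joins most readily: avg- and max-linkage
        partitions always refine the min-linkage partition (one agreeing
        cross edge implies single-linkage connectivity), and min linkage
        never yields more clusters than the other two. No refinement
        relation holds between avg and max: complete-linkage clusters
        need not nest inside UPGMA clusters."""
        for seed in range(6):
            recs = make_records(12, length=30, seed=seed, mutate_from_common=True)
            m = identity_matrix(recs)
            ladders = {
                lk: build_agglomerative_ladder(recs, lk, matrix=m)
                for lk in ("min", "max", "avg")
            }
            for lv in range(26):
                p_min = ladders["min"].rings[lv].member_sets()
                p_avg = ladders["avg"].rings[lv].member_sets()
                p_max = ladders["max"].rings[lv].member_sets()
                assert is_refinement(p_avg, p_min)
                assert is_refinement(p_max, p_min)
                assert len(p_min) <= min(len(p_avg), len(p_max))


class TestLadderIO:
    def test_tsv_roundtrip(self, tmp_path):
        recs = make_records(12, length=30, seed=17, mutate_from_common=True)
        lad = build_divisive_ladder(recs)
        p = tmp_path / "ladder.tsv"
        write_ladder(lad, recs, p)
        back = read_ladder(p, {r.id: i for i, r in enumerate(recs)})
        assert back.method == "centroid"
        assert back.cutoffs == lad.cutoffs
        for r1, r2 in zip(lad.rings, back.rings):
            assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]
            assert [(c.g1, c.g2) for c in r1.clusters] == [
                (c.g1, c.g2) for c in r2.clusters
            ]
        assert back.parent_of == lad.parent_of

    def test_default_cutoffs(self):
        cs = default_cutoffs()
        assert len(cs) == 26
        assert cs[0] == 0.75 and cs[-1] == 1.0
        assert all(round(b - a, 10) == 0.01 for a, b in zip(cs, cs[1:]))
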
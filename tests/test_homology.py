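"""Homology clustering: seeded hit generation, SiLiX-style single linkage,
the greedy centroid baseline, paralog filtering and the efficiency metric."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radphy import (
    all_vs_all_hits,
    clustering_efficiency,
    filter_paralogous_clusters,
    greedy_centroid_cluster,
    single_linkage_cluster,
)
from radphy.homology import ClusterParams, ClusterSet, PairHit, global_identity
from radphy._seq import decode, revcomp


def rand_seq(rng, n=85):
    return decode(rng.integers(0, 4, n).astype(np.uint8))


def mk_hit(q, s, identity=1.0, overlap=1.0):
    return PairHit(
        query=q, subject=s, identity=identity, overlap=overlap, evalue=1e-30,
        strand="+", score=85.0, aligned_columns=85, mismatches=0, gaps=0,
        q_start=0, q_end=85, s_start=0, s_end=85,
    )


class TestAllVsAllHits:
    def test_identical_sequences_perfect_hit(self, rng):
        s = rand_seq(rng)
        (hit,) = all_vs_all_hits({"a": s, "b": s})
        assert (hit.identity, hit.overlap, hit.strand) == (1.0, 1.0, "+")
        assert hit.evalue < 1e-4

    def test_reverse_complement_hits_minus_strand(self, rng):
        s = rand_seq(rng)
        (hit,) = all_vs_all_hits({"a": s, "b": revcomp(s)})
        assert hit.strand == "-" and hit.identity == 1.0

    def test_random_pairs_rarely_hit(self, rng):
        # E-value calibration: unrelated pairs essentially never reported
        n_hits = 0
        trials = 300
        for _ in range(trials):
            n_hits += len(all_vs_all_hits({"a": rand_seq(rng), "b": rand_seq(rng)}))
        assert n_hits / trials <= 0.01

    def test_low_complexity_seed_excluded(self, rng):
        # the only shared word is a poly-A run: entropy filter blocks seeding
        left, right = rand_seq(rng, 30), rand_seq(rng, 30)
        s1 = left + "A" * 14 + rand_seq(rng, 30)
        s2 = rand_seq(rng, 30) + "A" * 14 + right
        assert all_vs_all_hits({"a": s1, "b": s2}) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all_hits({})

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(min_identity=1.2)
        with pytest.raises(ValueError):
            ClusterParams(word_size=2)
        with pytest.raises(ValueError):
            ClusterParams(evalue_cut=0)


class TestSingleLinkage:
    def test_transitivity(self):
        cs = single_linkage_cluster(["A", "B", "C"], [mk_hit("A", "B"), mk_hit("B", "C")], 0.35, 0.35)
        assert cs.families == [["A", "B", "C"]]

    def test_threshold_boundary(self):
        cs = single_linkage_cluster(["A", "B"], [mk_hit("A", "B", identity=0.34)], 0.35, 0.35)
        assert cs.families == [["A"], ["B"]]
        cs = single_linkage_cluster(["A", "B"], [mk_hit("A", "B", identity=0.35)], 0.35, 0.35)
        assert cs.families == [["A", "B"]]

    def test_overlap_threshold(self):
        cs = single_linkage_cluster(["A", "B"], [mk_hit("A", "B", overlap=0.2)], 0.35, 0.35)
        assert len(cs.families) == 2

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            single_linkage_cluster(["A"], [mk_hit("A", "Z")], 0.35, 0.35)

    def test_hit_order_invariance(self, rng):
        ids = [f"s{i}" for i in range(20)]
        hits = []
        for _ in range(30):
            i, j = rng.choice(20, 2, replace=False)
            hits.append(mk_hit(ids[i], ids[j], identity=float(rng.uniform(0.2, 1.0))))
        ref = single_linkage_cluster(ids, hits, 0.5, 0.35).families
        for _ in range(5):
            rng.shuffle(hits)
            assert single_linkage_cluster(ids, hits, 0.5, 0.35).families == ref

    def test_matches_brute_force_closure(self, rng):
        # oracle equivalence on random hit graphs
        for _ in range(50):
            n = int(rng.integers(2, 30))
            ids = [f"s{i}" for i in range(n)]
            edges = set()
            hits = []
            for _ in range(int(rng.integers(0, 3 * n))):
                i, j = sorted(rng.choice(n, 2, replace=False).tolist())
                ident = float(rng.uniform(0, 1))
                hits.append(mk_hit(ids[i], ids[j], identity=ident))
                if ident >= 0.5:
                    edges.add((i, j))
            got = {frozenset(f) for f in single_linkage_cluster(ids, hits, 0.5, 0.35).families}
            adj = {i: set() for i in range(n)}
            for i, j in edges:
                adj[i].add(j)
                adj[j].add(i)
            comps, seen = set(), set()
            for i in range(n):
                if i in seen:
                    continue
                comp, stack = set(), [i]
                while stack:
                    c = stack.pop()
                    if c in comp:
                        continue
                    comp.add(c)
                    stack.extend(adj[c])
                seen |= comp
                comps.add(frozenset(ids[k] for k in comp))
            assert got == comps


class TestGreedyCentroid:
    def test_identical_sequences_one_cluster(self, rng):
        s = rand_seq(rng)
        cs = greedy_centroid_cluster({"a": s, "b": s, "c": s}, 0.9)
        assert cs.families == [["a", "b", "c"]]

    def test_order_dependence(self):
        # chain A~B~C with identity(A,C) below threshold: the partition
        # depends on which sequence seeds the first centroid
        b = "ACGTACGTACGTACGTACGT"
        a = "TGCAT" + b[5:]  # every substituted position differs from b
        c = b[:15] + "GCTAC"
        assert global_identity(a, b, both_strands=False) == 0.75
        assert global_identity(b, c, both_strands=False) == 0.75
        assert global_identity(a, c, both_strands=False) == 0.5
        seqs = {"A": a, "B": b, "C": c}
        split = greedy_centroid_cluster(seqs, 0.7, seed_order=["A", "B", "C"], both_strands=False)
        joined = greedy_centroid_cluster(seqs, 0.7, seed_order=["B", "A", "C"], both_strands=False)
        assert sorted(map(len, split.families)) == [1, 2]
        assert sorted(map(len, joined.families)) == [3]

    def test_identity_one_groups_exact_duplicates(self, rng):
        s1, s2 = rand_seq(rng), rand_seq(rng)
        cs = greedy_centroid_cluster({"a": s1, "b": s1, "c": s2}, 1.0)
        assert {frozenset(f) for f in cs.families} == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_seed_order_must_be_permutation(self, rng):
        with pytest.raises(ValueError):
            greedy_centroid_cluster({"a": rand_seq(rng)}, 0.5, seed_order=["b"])


class TestParalogFilter:
    def test_two_loci_from_one_specimen_removed(self):
        cs = ClusterSet(families=[["x|1", "x|2", "y|1"], ["x|3", "y|2"]], provenance="single_linkage")
        spec = {"x|1": "x", "x|2": "x", "x|3": "x", "y|1": "y", "y|2": "y"}
        kept, removed, frac = filter_paralogous_clusters(cs, spec)
        assert kept.families == [["x|3", "y|2"]]
        assert removed.families == [["x|1", "x|2", "y|1"]]
        assert frac == pytest.approx(3 / 5)

    def test_paralog_free_input_untouched(self):
        cs = ClusterSet(families=[["x|1", "y|1"]], provenance="single_linkage")
        kept, removed, frac = filter_paralogous_clusters(cs, {"x|1": "x", "y|1": "y"})
        assert removed.families == [] and frac == 0.0


class TestEfficiency:
    def test_perfect_recovery(self):
        cs = ClusterSet(families=[["a1", "b1"], ["a2", "b2"]], provenance="single_linkage")
        truth = {"a1": 1, "b1": 1, "a2": 2, "b2": 2}
        assert clustering_efficiency(cs, truth, 2) == 1.0

    def test_partial_recovery(self):
        fams = [[f"a{i}", f"b{i}"] for i in range(8)] + [["a8", "b8", "a9"], ["b9"]]
        truth = {f"{s}{i}": i for i in range(10) for s in "ab"}
        cs = ClusterSet(families=fams, provenance="single_linkage")
        assert clustering_efficiency(cs, truth, 2) == pytest.approx(0.8)

    def test_paralog_inclusion_counts_as_unrecovered(self):
        # the group is gathered but impure: not recovered
        cs = ClusterSet(families=[["a1", "b1", "paralog"]], provenance="single_linkage")
        truth = {"a1": 1, "b1": 1, "paralog": 2}
        assert clustering_efficiency(cs, truth, 2) == 0.0

    def test_min_species_validation(self):
        cs = ClusterSet(families=[["a"]], provenance="single_linkage")
        with pytest.raises(ValueError):
            clustering_efficiency(cs, {"a": 1}, 1)


@given(
    st.lists(st.tuples(st.integers(0, 11), st.integers(0, 11), st.floats(0, 1)), max_size=40)
)
def test_partition_invariants_single_linkage(edges):
    """Any hit graph yields a valid partition: disjoint families covering
    every id exactly once."""
    ids = [f"s{i}" for i in range(12)]
    hits = [mk_hit(ids[i], ids[j], identity=w) for i, j, w in edges if i != j]
    cs = single_linkage_cluster(ids, hits, 0.5, 0.35)
    members = [x for fam in cs.families for x in fam]
    assert sorted(members) == sorted(ids)


@given(st.lists(st.integers(0, 3), min_size=4, max_size=4), st.integers(0, 2**31 - 1))
def test_partition_invariants_greedy(lengths_idx, seed):
    rng = np.random.default_rng(seed)
    seqs = {f"s{i}": rand_seq(rng, 20 + 5 * k) for i, k in enumerate(lengths_idx)}
    cs = greedy_centroid_cluster(seqs, 0.6)
    members = [x for fam in cs.families for x in fam]
    assert sorted(members) == sorted(seqs)
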
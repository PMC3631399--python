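"""Supermatrix construction, distances, neighbor joining, bootstrap and
Robinson-Foulds scoring."""

import math

import dendropy
import numpy as np
import pytest

from radphy import (
    align_family,
    bootstrap_support,
    build_supermatrix,
    distance_matrix,
    nj_tree,
    rf_distance,
)
from radphy.phylo import Supermatrix, bipartitions, informative_loci_per_node
from radphy._seq import decode


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def sm_from_rows(rows):
    taxa = sorted(rows)
    width = len(next(iter(rows.values())))
    return Supermatrix(
        taxa=taxa,
        rows=rows,
        spans=[("C0", 0, width)],
        gap_fraction={t: rows[t].count("-") / width for t in taxa},
    )


class TestAlignFamily:
    def test_identical_members(self):
        fam = align_family("C0", {"x": "ACGT", "y": "ACGT"})
        assert fam.width == 4 and fam.rows["x"] == "ACGT"

    def test_short_member_right_padded(self):
        fam = align_family("C0", {"x": "A" * 85, "y": "C" * 35})
        assert fam.rows["y"] == "C" * 35 + "-" * 50

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            align_family("C0", {})


class TestSupermatrix:
    def _families(self):
        return [
            align_family("C0", {t: "A" * 85 for t in "wxyz"}),
            align_family("C1", {t: "C" * 85 for t in "wxy"}),
            align_family("C2", {t: "G" * 85 for t in "wxyz"}),
        ]

    def test_min_taxa_filter_and_width(self):
        sm = build_supermatrix(self._families(), min_taxa=4)
        assert sm.width == 170
        assert [s[0] for s in sm.spans] == ["C0", "C2"]

    def test_gap_fill_and_fractions(self):
        sm = build_supermatrix(self._families(), min_taxa=3)
        assert sm.width == 255
        assert sm.gap_fraction["w"] == 0.0
        assert sm.rows["z"][85:170] == "-" * 85
        assert sm.gap_fraction["z"] == pytest.approx(85 / 255)

    def test_no_qualifying_family(self):
        with pytest.raises(ValueError):
            build_supermatrix(self._families(), min_taxa=5)


class TestDistances:
    def test_p_distance(self):
        sm = sm_from_rows({"x": "AAAA", "y": "AAAT"})
        D, taxa = distance_matrix(sm, "p")
        assert D[0, 1] == pytest.approx(0.25)

    def test_jc_correction(self):
        sm = sm_from_rows({"x": "AAAA", "y": "AAAT"})
        D, _ = distance_matrix(sm, "jc")
        assert D[0, 1] == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-9)
        assert D[0, 1] == pytest.approx(0.3041, abs=1e-4)

    def test_identical_rows_zero(self):
        sm = sm_from_rows({"x": "ACGT", "y": "ACGT"})
        for corr in ("p", "jc"):
            assert distance_matrix(sm, corr)[0][0, 1] == 0.0

    def test_pairwise_deletion(self):
        sm = sm_from_rows({"x": "AA--", "y": "A-A-", "z": "AAAA"})
        D, taxa = distance_matrix(sm, "p")
        assert D[taxa.index("x"), taxa.index("z")] == 0.0

    def test_no_shared_columns_fails_loudly(self):
        sm = sm_from_rows({"x": "AA--", "y": "--AA"})
        with pytest.raises(ValueError, match="shares no ungapped columns"):
            distance_matrix(sm, "p")

    def test_saturated_jc_undefined(self):
        sm = sm_from_rows({"x": "AAAA", "y": "CCCC"})
        D, _ = distance_matrix(sm, "jc")
        assert np.isnan(D[0, 1])
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = float("nan")
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(bad, ["x", "y", "z"])


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)): NJ must reproduce the
        # metric exactly (additivity)
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, labels)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j])

    def test_three_taxon_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_ultrametric_eight_taxa(self):
        newick = "((((a:1,b:1):1,(c:1.5,d:1.5):0.5):1,(e:2,f:2):1):1,(g:3,h:3):1);"
        truth = tree_from(newick)
        pdm = truth.phylogenetic_distance_matrix()
        taxa = sorted(truth.taxon_namespace, key=lambda t: t.label)
        D = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        inferred = nj_tree(D, [t.label for t in taxa])
        assert rf_distance(inferred, truth) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])
        D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("abc"))

    def test_agrees_with_independent_nj_implementation(self, rng):
        # cross-check against scikit-bio on a random additive matrix
        import skbio

        labels = [f"t{i}" for i in range(7)]
        truth = _random_additive_tree(labels, rng)
        D, _ = _tree_distances(truth, labels)
        mine = nj_tree(D, labels)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        theirs = tree_from(str(sk))
        assert rf_distance(mine, theirs) == 0


def _random_additive_tree(labels, rng):
    items = [f"{l}:{rng.uniform(0.1, 1.0):.4f}" for l in labels]
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), 2, replace=False).tolist(), reverse=True)
        a, b = items.pop(i), items.pop(j)
        items.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.4f}")
    return tree_from(f"({items[0]},{items[1]});")


def _tree_distances(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return D, labels


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = tree_from("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, tree_from("((a:1,b:1):1,(c:1,d:1):1);")) == 0

    def test_four_taxon_swap(self):
        t1 = tree_from("((a,b),(c,d));")
        t2 = tree_from("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_star_vs_binary(self):
        star = tree_from("(a,b,c,d,e);")
        binary = tree_from("(((a,b),c),(d,e));")
        assert rf_distance(star, binary) == 2

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError):
            rf_distance(tree_from("(a,b,c);"), tree_from("(a,b,d);"))


class TestBootstrap:
    def _signal_supermatrix(self, rng, tree_newick, width=4000):
        from radphy import evolve_along_tree, generate_ancestor

        anc = generate_ancestor(width, 0.5, seed=31)
        leaves = evolve_along_tree(anc, tree_from(tree_newick), seed=31)
        return sm_from_rows({t: g.sequence for t, g in leaves.items()})

    def test_single_replicate_supports_binary(self, rng):
        sm = self._signal_supermatrix(rng, "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);", 500)
        st = bootstrap_support(sm, reps=1, seed=1)
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_strong_signal_full_support(self, rng):
        newick = (
            "(((((a:.05,b:.05):.05,c:.1):.05,d:.15):.05,(e:.1,f:.1):.1):.05,"
            "((g:.1,h:.1):.05,(i:.08,j:.08):.07):.1);"
        )
        sm = self._signal_supermatrix(rng, newick, 6000)
        st = bootstrap_support(sm, reps=100, seed=2)
        assert st.min_support >= 95
        assert rf_distance(st.tree, tree_from(newick)) == 0

    def test_destroyed_signal_low_support(self, rng):
        # iid rows carry no phylogenetic signal: supports collapse
        rows = {f"t{i}": decode(rng.integers(0, 4, 3000).astype(np.uint8)) for i in range(8)}
        st = bootstrap_support(sm_from_rows(rows), reps=100, seed=3, correction="p")
        assert st.min_support < 80

    def test_reps_validation(self, rng):
        sm = sm_from_rows({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        with pytest.raises(ValueError):
            bootstrap_support(sm, reps=0, seed=1)


class TestInformativeLoci:
    def test_counting_rules(self):
        tree = tree_from("(((a,b),c),(d,e));")
        all_taxa = {"a", "b", "c", "d", "e"}
        fams = [all_taxa, {"a", "b"}, {"a", "b", "c"}, {"d", "e", "a"}]
        counts = informative_loci_per_node(fams, tree)
        # clade {a,b}: needs a, b and an outsider
        assert counts[frozenset({"a", "b"})] == 2  # full family + {a,b,c}
        # clade {a,b,c}: needs one of {a,b}, c, and an outsider
        assert counts[frozenset({"a", "b", "c"})] == 1  # only the full family
        assert counts[frozenset({"d", "e"})] == 2  # full family + {d,e,a}

    def test_family_with_all_taxa_counts_everywhere(self):
        tree = tree_from("(((a,b),c),(d,e));")
        counts = informative_loci_per_node([{"a", "b", "c", "d", "e"}], tree)
        assert all(v == 1 for v in counts.values())
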
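"""Supermatrix construction and distance-based tree inference.

Homolog families are concatenated into a gap-filled supermatrix (taxa
absent from a family get '-' across its span), pairwise distances are
computed with pairwise deletion under a p-distance or Jukes-Cantor
correction, a neighbor-joining tree is inferred with deterministic
tie-breaking, and branch support is obtained by resampling alignment
columns with replacement. Robinson-Foulds distance to the true species
tree operationalizes "topology recovered".

Because the simulator is indel-free and tags are anchored at the
restriction site, family alignment is positional: column k is position k;
rows of unequal length (e.g. 35-bp tags mixed with 85-bp tags) are
right-padded with gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from ._rng import substream
from ._seq import encode

GAP_CODE = 4

__all__ = [
    "FamilyAlignment",
    "Supermatrix",
    "SupportedTree",
    "align_family",
    "build_supermatrix",
    "distance_matrix",
    "nj_tree",
    "bipartitions",
    "rf_distance",
    "bootstrap_support",
    "informative_loci_per_node",
]


@dataclass
class FamilyAlignment:
    cluster_id: str
    rows: dict[str, str]  # taxon -> aligned sequence
    width: int

    @property
    def taxa(self) -> set[str]:
        return set(self.rows)


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    spans: list[tuple[str, int, int]]  # (cluster_id, start, end)
    gap_fraction: dict[str, float]

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def encoded(self) -> np.ndarray:
        out = np.empty((len(self.taxa), self.width), dtype=np.uint8)
        for i, taxon in enumerate(self.taxa):
            row = self.rows[taxon]
            codes = np.frombuffer(row.replace("-", "N").encode(), dtype=np.uint8)
            enc = np.full(self.width, GAP_CODE, dtype=np.uint8)
            not_gap = codes != ord("N")
            if not_gap.any():
                enc[not_gap] = encode("".join(c for c in row if c != "-"))
            out[i] = enc
        return out


@dataclass
class SupportedTree:
    tree: dendropy.Tree
    supports: dict[frozenset, float]  # bipartition -> percentage in [0, 100]

    @property
    def min_support(self) -> float:
        return min(self.supports.values()) if self.supports else float("nan")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def align_family(cluster_id: str, members: Mapping[str, str]) -> FamilyAlignment:
    """Positional alignment of oriented, site-anchored tags; shorter rows
    are right-padded with '-'."""
    if not members:
        raise ValueError("empty family")
    width = max(len(s) for s in members.values())
    rows = {taxon: seq + "-" * (width - len(seq)) for taxon, seq in members.items()}
    return FamilyAlignment(cluster_id=cluster_id, rows=rows, width=width)


def build_supermatrix(families: Sequence[FamilyAlignment], min_taxa: int = 4) -> Supermatrix:
    """Concatenate families with >= min_taxa distinct taxa (in cluster-id
    order), gap-filling missing taxa."""
    kept = sorted((f for f in families if len(f.taxa) >= min_taxa), key=lambda f: f.cluster_id)
    if not kept:
        raise ValueError(f"no family has >= {min_taxa} taxa")
    taxa = sorted(set().union(*(f.taxa for f in kept)))
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    spans = []
    pos = 0
    for fam in kept:
        for t in taxa:
            parts[t].append(fam.rows.get(t, "-" * fam.width))
        spans.append((fam.cluster_id, pos, pos + fam.width))
        pos += fam.width
    rows = {t: "".join(parts[t]) for t in taxa}
    gap_fraction = {t: rows[t].count("-") / pos for t in taxa}
    return Supermatrix(taxa=taxa, rows=rows, spans=spans, gap_fraction=gap_fraction)


def _pairwise_distances(enc: np.ndarray, correction: str) -> np.ndarray:
    n = enc.shape[0]
    D = np.zeros((n, n))
    valid = enc != GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"taxon pair ({i}, {j}) shares no ungapped columns; "
                    "distances are undefined"
                )
            p = float((enc[i, shared] != enc[j, shared]).mean())
            if correction == "p":
                d = p
            elif correction == "jc":
                d = float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
            else:
                raise ValueError(f"unknown correction {correction!r}")
            D[i, j] = D[j, i] = d
    return D


def distance_matrix(sm: Supermatrix, correction: str = "jc") -> tuple[np.ndarray, list[str]]:
    """Pairwise-deletion distances between supermatrix rows. Returns the
    symmetric matrix and the taxon order. p >= 0.75 under the JC correction
    yields NaN (undefined distance)."""
    return _pairwise_distances(sm.encoded(), correction), list(sm.taxa)


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking by taxon label
    order. Negative branch-length estimates are clamped to zero. Returns an
    unrooted tree (trifurcating root) recovering additive matrices exactly.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n != D.shape[1] or n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any() or np.isinf(D).any():
        raise ValueError("distance matrix contains undefined entries")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")

    # each active item: (newick fragment, min leaf label for tie-breaking)
    items = [(label, label) for label in labels]
    D = D.copy()

    while len(items) > 3:
        m = len(items)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + 1e-12
        ]
        i, j = min(ties, key=lambda ij: tuple(sorted((items[ij[0]][1], items[ij[1]][1]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick = f"({items[i][0]}:{li:.10g},{items[j][0]}:{lj:.10g})"
        tag = min(items[i][1], items[j][1])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_next[: m - 2, m - 2] = D_next[m - 2, : m - 2] = d_new[keep]
        D_next[m - 2, m - 2] = 0.0
        D = D_next
        items = [items[k] for k in keep] + [(newick, tag)]

    # final star over three items with exact branch lengths
    (a, b, c) = (0, 1, 2)
    la = max(0.0, 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = max(0.0, 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = max(0.0, 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    newick = (
        f"({items[a][0]}:{la:.10g},{items[b][0]}:{lb:.10g},{items[c][0]}:{lc:.10g});"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each canonicalized as the side
    NOT containing the alphabetically first taxon."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance: bipartitions present in exactly
    one of the two trees."""
    leaves_a = {l.taxon.label for l in tree_a.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tree_b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees must share an identical leaf set")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def bootstrap_support(
    sm: Supermatrix, reps: int = 100, seed: int = 0, correction: str = "jc"
) -> SupportedTree:
    """NJ tree on the full supermatrix, with per-internal-edge support =
    percentage of column-resampled replicates containing the same
    bipartition."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    enc = sm.encoded()
    base = nj_tree(*distance_matrix(sm, correction))
    base_bips = bipartitions(base)
    counts = {bip: 0 for bip in base_bips}
    rng = substream(seed, "bootstrap")
    W = enc.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, W, size=W)
        rep_tree = nj_tree(_pairwise_distances(enc[:, cols], correction), list(sm.taxa))
        for bip in bipartitions(rep_tree):
            if bip in counts:
                counts[bip] += 1
    supports = {bip: 100.0 * c / reps for bip, c in counts.items()}
    _annotate_supports(base, supports)
    return SupportedTree(tree=base, supports=supports)


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"


def informative_loci_per_node(
    families: Sequence[FamilyAlignment] | Sequence[set],
    tree: dendropy.Tree,
) -> dict[frozenset, int]:
    """For each internal node of the rooted tree (root excluded: it has no
    outgroup), the number of families with >= 1 taxon in every child clade
    and >= 1 taxon outside the node's clade. Keys are the node's leaf sets.
    """
    fam_taxa = [f.taxa if isinstance(f, FamilyAlignment) else set(f) for f in families]
    all_taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    out: dict[frozenset, int] = {}
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        clades = [
            {l.taxon.label for l in child.leaf_iter()} for child in node.child_nodes()
        ]
        clade_all = set().union(*clades)
        outside = all_taxa - clade_all
        if not outside:
            continue
        count = sum(
            1
            for taxa in fam_taxa
            if taxa & outside and all(taxa & c for c in clades)
        )
        out[frozenset(clade_all)] = count
    return out
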
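"""Synthetic genome evolution with exact positional truth.

An ancestral genome of i.i.d. bases is evolved along a species tree under a
Jukes-Cantor-like substitution-only model. Because there are no indels,
position *i* in every descendant is homologous to position *i* in the
ancestor; the truth map is simply carried along. Segmental duplications are
the only operation that creates new homology relationships: a duplicated
window keeps the ancestral coordinates of its source but receives a fresh
duplication-lineage tag, so downstream evaluation can label tag pairs as
orthologous (same coordinate, same lineage) or paralogous (same coordinate,
different lineage).

Heterozygosity is modelled by simulating a second haplotype per specimen:
each site of the first haplotype mutates independently with probability
``h``, giving a realized allele distance of ~h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from ._rng import substream
from ._seq import decode, mutate

__all__ = [
    "HaploidGenome",
    "DiploidGenome",
    "generate_ancestor",
    "evolve_along_tree",
    "insert_duplications",
    "diploidize",
    "p_distance",
    "jc_expected_p_distance",
    "jc_p_sub",
    "simulate_tag_families",
]


@dataclass
class HaploidGenome:
    """One haplotype with its positional truth.

    ``anc_coord[i]`` is the ancestral coordinate of position ``i`` and
    ``lineage[i]`` its duplication-lineage tag (0 for the original copy).
    Arrays may be shared between genomes related by substitution-only
    evolution; they are copied on write only by :func:`insert_duplications`.
    """

    taxon: str
    seq: np.ndarray
    anc_coord: np.ndarray
    lineage: np.ndarray
    _sequence_cache: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.seq.size == 0:
            raise ValueError("genome length must be positive")
        if len(self.anc_coord) != len(self.seq) or len(self.lineage) != len(self.seq):
            raise ValueError("coord_map length must equal sequence length")

    def __len__(self) -> int:
        return int(self.seq.size)

    @property
    def sequence(self) -> str:
        if self._sequence_cache is None:
            self._sequence_cache = decode(self.seq)
        return self._sequence_cache

    def site_identity(self, position: int) -> tuple[int, int]:
        """(ancestral coordinate, lineage tag) at a position."""
        return int(self.anc_coord[position]), int(self.lineage[position])


@dataclass
class DiploidGenome:
    """Two equal-length haplotypes of one specimen."""

    specimen: str
    haplotype_a: HaploidGenome
    haplotype_b: HaploidGenome
    h: float

    def __post_init__(self) -> None:
        if len(self.haplotype_a) != len(self.haplotype_b):
            raise ValueError("haplotypes must have identical length")

    @property
    def realized_heterozygosity(self) -> float:
        return float(np.mean(self.haplotype_a.seq != self.haplotype_b.seq))


def jc_p_sub(d: float) -> float:
    """Per-site substitution probability over a branch of length ``d``
    expected substitutions/site (Jukes-Cantor)."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_expected_p_distance(d: float) -> float:
    """Expected observed p-distance between the two ends of a path of total
    length ``d`` substitutions/site. Identical to :func:`jc_p_sub` because
    JC substitution processes are additive along a path."""
    return jc_p_sub(d)


def generate_ancestor(length: int, gc: float, seed: int, taxon: str = "ancestor") -> HaploidGenome:
    """I.i.d. ancestral genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = substream(seed, "ancestor")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return HaploidGenome(
        taxon=taxon,
        seq=seq,
        anc_coord=np.arange(length, dtype=np.int64),
        lineage=np.zeros(length, dtype=np.int32),
    )


def evolve_along_tree(
    ancestor: HaploidGenome, tree: dendropy.Tree, seed: int
) -> dict[str, HaploidGenome]:
    """Evolve the ancestor down every branch of ``tree``; returns the leaf
    genomes keyed by taxon label. Coordinates are inherited unchanged."""
    rng = substream(seed, "evolve")
    node_seq: dict[int, np.ndarray] = {}
    leaves: dict[str, HaploidGenome] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = ancestor.seq
        else:
            d = node.edge.length if node.edge.length is not None else 0.0
            if d < 0:
                raise ValueError(f"negative branch length {d}")
            seq = mutate(node_seq[id(node.parent_node)], jc_p_sub(d), rng)
        node_seq[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label
            leaves[label] = HaploidGenome(
                taxon=label, seq=seq, anc_coord=ancestor.anc_coord, lineage=ancestor.lineage
            )
    return leaves


def insert_duplications(
    genome: HaploidGenome,
    n_dup: int,
    dup_len: int,
    post_dup_divergence: float,
    seed: int,
    max_fraction: float = 0.25,
    sources: "Sequence[int] | None" = None,
) -> HaploidGenome:
    """Copy ``n_dup`` random windows of ``dup_len`` bp to random
    non-overlapping destinations (the destination window is overwritten, so
    genome length and positional truth stay exact). Each copy mutates per
    site with probability ``post_dup_divergence`` and receives a fresh
    lineage tag, marking it paralogous to its source. ``sources`` optionally
    pins the source start positions (defaults to uniform random)."""
    L = len(genome)
    if dup_len >= L:
        raise ValueError("dup_len must be smaller than the genome")
    if n_dup * dup_len > max_fraction * L:
        raise ValueError(
            f"{n_dup} duplications of {dup_len} bp exceed {max_fraction:.0%} of the genome"
        )
    if n_dup == 0:
        return genome
    rng = substream(seed, f"duplications:{genome.taxon}")
    seq = genome.seq.copy()
    anc = genome.anc_coord.copy()
    lin = genome.lineage.copy()
    if sources is not None and len(sources) != n_dup:
        raise ValueError("sources must have one start position per duplication")
    next_tag = int(lin.max()) + 1
    for k in range(n_dup):
        src = int(sources[k]) if sources is not None else int(rng.integers(0, L - dup_len + 1))
        while True:
            dst = int(rng.integers(0, L - dup_len + 1))
            if dst + dup_len <= src or dst >= src + dup_len:
                break
        window = mutate(seq[src : src + dup_len], post_dup_divergence, rng)
        seq[dst : dst + dup_len] = window
        anc[dst : dst + dup_len] = anc[src : src + dup_len]
        lin[dst : dst + dup_len] = next_tag
        next_tag += 1
    return HaploidGenome(taxon=genome.taxon, seq=seq, anc_coord=anc, lineage=lin)


def diploidize(genome: HaploidGenome, h: float, seed: int) -> DiploidGenome:
    """Second haplotype = first with independent per-site mutation at
    probability ``h`` (target allele distance)."""
    if not 0.0 <= h <= 0.2:
        raise ValueError(f"heterozygosity must be in [0, 0.2], got {h}")
    rng = substream(seed, f"diploidize:{genome.taxon}")
    hap_b = HaploidGenome(
        taxon=genome.taxon,
        seq=mutate(genome.seq, h, rng),
        anc_coord=genome.anc_coord,
        lineage=genome.lineage,
    )
    return DiploidGenome(specimen=genome.taxon, haplotype_a=genome, haplotype_b=hap_b, h=h)


def p_distance(a: HaploidGenome, b: HaploidGenome) -> float:
    """Fraction of differing sites between two equal-length genomes."""
    if len(a) != len(b):
        raise ValueError("p-distance requires equal-length genomes")
    return float(np.mean(a.seq != b.seq))


def simulate_tag_families(
    tree: dendropy.Tree,
    n_families: int,
    tag_len: int,
    seed: int,
) -> tuple[dict[str, str], dict[str, int], dict[str, str]]:
    """Independent ortholog families: one random ancestral tag per family,
    evolved along ``tree``. Returns (sequences by id, truth family index by
    id, specimen by id); ids are ``{taxon}|fam{k}``."""
    rng = substream(seed, "tag-families")
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seqs: dict[str, str] = {}
    truth: dict[str, int] = {}
    specimen_of: dict[str, str] = {}
    for k in range(n_families):
        root = rng.integers(0, 4, size=tag_len).astype(np.uint8)
        node_seq: dict[int, np.ndarray] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                s = root
            else:
                d = node.edge.length or 0.0
                s = mutate(node_seq[id(node.parent_node)], jc_p_sub(d), rng)
            node_seq[id(node)] = s
            if node.is_leaf():
                sid = f"{node.taxon.label}|fam{k}"
                seqs[sid] = decode(s)
                truth[sid] = k
                specimen_of[sid] = node.taxon.label
    # deterministic id order regardless of tree traversal details
    order = sorted(seqs)
    return ({i: seqs[i] for i in order}, {i: truth[i] for i in order}, {i: specimen_of[i] for i in order})
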
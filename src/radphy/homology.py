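"""Cross-specimen homology clustering of locus consensus sequences.

Two clustering strategies are provided:

* :func:`single_linkage_cluster` -- a SiLiX-style partition: all-vs-all
  seeded local alignments produce pairwise hits; hits passing identity and
  overlap thresholds become edges of a graph whose connected components
  (union-find) are the putative homolog families. Transitivity lets deep
  homologs join a family through intermediate relatives even when their
  direct similarity is undetectable.

* :func:`greedy_centroid_cluster` -- a uclust-style baseline: sequences are
  processed in a seed order and each either joins the first centroid whose
  global-alignment identity reaches the threshold, or founds a new
  centroid. The result is order dependent by construction.

Hit generation follows the BLASTN recipe at small scale: candidate pairs
must share an exact ``word_size``-mer (either strand) whose entropy is at
least 1.5 bits/base (a low-complexity filter), a Smith-Waterman local
alignment is computed for candidates, and hits are kept when the
Karlin-Altschul E-value E = K*m*n*exp(-lambda*S) of the alignment score is
at most the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import DisjointSet
from scipy.optimize import brentq

from ._seq import revcomp

__all__ = [
    "ClusterParams",
    "PairHit",
    "ClusterSet",
    "all_vs_all_hits",
    "single_linkage_cluster",
    "greedy_centroid_cluster",
    "global_identity",
    "filter_paralogous_clusters",
    "clustering_efficiency",
]

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
KA_K = 0.621  # Karlin-Altschul K for +1/-2 nucleotide scoring
MIN_SEED_ENTROPY = 1.5  # bits/base


@dataclass(frozen=True)
class ClusterParams:
    min_identity: float = 0.35
    min_overlap: float = 0.35
    evalue_cut: float = 1e-4
    word_size: int = 11

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_overlap <= 1):
            raise ValueError("identity and overlap thresholds must be in [0, 1]")
        if self.evalue_cut <= 0:
            raise ValueError("evalue_cut must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclass(frozen=True)
class PairHit:
    query: str
    subject: str
    identity: float  # matches / aligned columns
    overlap: float  # aligned columns / max(len(query), len(subject))
    evalue: float
    strand: str  # "+" | "-"
    score: float
    aligned_columns: int
    mismatches: int
    gaps: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


@dataclass
class ClusterSet:
    """A partition of sequence ids into disjoint families."""

    families: list[list[str]]
    provenance: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            for sid in fam:
                if sid in seen:
                    raise ValueError(f"id {sid!r} appears in more than one family")
                seen.add(sid)

    @property
    def ids(self) -> set[str]:
        return {sid for fam in self.families for sid in fam}

    def as_mapping(self) -> dict[str, int]:
        return {sid: k for k, fam in enumerate(self.families) for sid in fam}

    def family_sets(self) -> list[frozenset[str]]:
        return [frozenset(f) for f in self.families]


@lru_cache(maxsize=1)
def _ka_lambda() -> float:
    """Ungapped Karlin-Altschul lambda for +1/-2 scoring on uniform bases:
    the positive root of 0.25*e^l + 0.75*e^(-2l) = 1."""
    return float(brentq(lambda l: 0.25 * math.exp(l) + 0.75 * math.exp(-2 * l) - 1, 0.2, 5.0))


def evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-_ka_lambda() * score)


def _word_entropy(word: str) -> float:
    counts = {c: word.count(c) for c in set(word)}
    n = len(word)
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def _seed_words(seq: str, w: int) -> set[str]:
    return {
        seq[i : i + w]
        for i in range(len(seq) - w + 1)
        if _word_entropy(seq[i : i + w]) >= MIN_SEED_ENTROPY
    }


def _local_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )


def _global_aligner() -> Align.PairwiseAligner:
    # stiff gap opening (uclust-like) so spurious internal gaps cannot
    # inflate the identity of unrelated sequences
    return Align.PairwiseAligner(
        mode="global",
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=-10,
        extend_gap_score=-1,
    )


def _hit_from_alignment(q_id, s_id, q_seq, s_seq, strand, aligner) -> PairHit | None:
    alns = aligner.align(q_seq if strand == "+" else revcomp(q_seq), s_seq)
    if len(alns) == 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return None
    e = evalue(aln.score, len(q_seq), len(s_seq))
    q_seg, s_seg = aln.aligned
    return PairHit(
        query=q_id,
        subject=s_id,
        identity=counts.identities / cols,
        overlap=cols / max(len(q_seq), len(s_seq)),
        evalue=e,
        strand=strand,
        score=float(aln.score),
        aligned_columns=int(cols),
        mismatches=int(counts.mismatches),
        gaps=int(counts.gaps),
        q_start=int(q_seg[0][0]),
        q_end=int(q_seg[-1][1]),
        s_start=int(s_seg[0][0]),
        s_end=int(s_seg[-1][1]),
    )


def all_vs_all_hits(seqs: Mapping[str, str], params: ClusterParams | None = None) -> list[PairHit]:
    """Seeded all-against-all local alignment hits with E <= cutoff.

    For every unordered pair sharing at least one qualifying word (on
    either strand) the local alignment is computed on the seeded strand(s)
    and the best (lowest E-value) alignment of the pair is reported.
    """
    params = params or ClusterParams()
    if not seqs:
        raise ValueError("empty input")
    ids = list(seqs)
    w = params.word_size
    fwd_words = {sid: _seed_words(seqs[sid], w) for sid in ids}
    rev_words = {sid: _seed_words(revcomp(seqs[sid]), w) for sid in ids}

    index: dict[str, list[int]] = {}
    for i, sid in enumerate(ids):
        for word in fwd_words[sid]:
            index.setdefault(word, []).append(i)

    candidates: dict[tuple[int, int], set[str]] = {}
    for i, sid in enumerate(ids):
        for word, members in ((word, index.get(word)) for word in fwd_words[sid]):
            if members:
                for j in members:
                    if j > i:
                        candidates.setdefault((i, j), set()).add("+")
        for word in rev_words[sid]:
            for j in index.get(word, ()):
                if j != i:
                    key = (i, j) if i < j else (j, i)
                    candidates.setdefault(key, set()).add("-")

    aligner = _local_aligner()
    hits: list[PairHit] = []
    for (i, j), strands in sorted(candidates.items()):
        best: PairHit | None = None
        for strand in sorted(strands):
            hit = _hit_from_alignment(ids[i], ids[j], seqs[ids[i]], seqs[ids[j]], strand, aligner)
            if hit is not None and (best is None or hit.evalue < best.evalue):
                best = hit
        if best is not None and best.evalue <= params.evalue_cut:
            hits.append(best)
    return hits


def single_linkage_cluster(
    ids: Iterable[str],
    hits: Sequence[PairHit],
    min_identity: float = 0.35,
    min_overlap: float = 0.35,
) -> ClusterSet:
    """Union-find over hits with identity >= i and overlap >= r; families
    are the connected components, ids without a qualifying edge are
    singletons. Invariant to hit order and id relabeling."""
    ids = list(ids)
    known = set(ids)
    ds = DisjointSet(ids)
    for hit in hits:
        if hit.query not in known or hit.subject not in known:
            raise KeyError(f"hit references unknown id: {hit.query!r}/{hit.subject!r}")
        if hit.identity >= min_identity and hit.overlap >= min_overlap:
            ds.merge(hit.query, hit.subject)
    families = sorted((sorted(fam) for fam in ds.subsets()), key=lambda f: f[0])
    return ClusterSet(families=families, provenance="single_linkage")


def global_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Global identity over the entire sequence length.

    RAD tags are anchored at the cut site and the mutation model is
    substitution-only, so for equal-length sequences the optimal global
    alignment is the ungapped one and identity is the fraction of matching
    positions (a gapped aligner would inflate the identity of unrelated
    sequences by fishing for chance matches). Unequal lengths fall back to
    a stiff-gap Needleman-Wunsch, normalized by the longer length."""

    def ident(x: str) -> float:
        if len(x) == len(b):
            xa, xb = np.frombuffer(x.encode(), np.uint8), np.frombuffer(b.encode(), np.uint8)
            return float((xa == xb).mean())
        aln = _global_aligner().align(x, b)[0]
        return aln.counts().identities / max(len(x), len(b))

    best = ident(a)
    if both_strands:
        best = max(best, ident(revcomp(a)))
    return best


def greedy_centroid_cluster(
    seqs: Mapping[str, str],
    min_identity: float = 0.35,
    seed_order: Sequence[str] | None = None,
    both_strands: bool = True,
) -> ClusterSet:
    """Greedy centroid clustering: each sequence, in seed order, joins the
    first existing centroid with global identity >= threshold or founds a
    new centroid. Order dependent (tested as such)."""
    if not seqs:
        raise ValueError("empty input")
    order = list(seed_order) if seed_order is not None else list(seqs)
    if set(order) != set(seqs):
        raise ValueError("seed_order must be a permutation of the sequence ids")
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        joined = False
        for cid in centroids:
            if global_identity(seqs[sid], seqs[cid], both_strands=both_strands) >= min_identity:
                members[cid].append(sid)
                joined = True
                break
        if not joined:
            centroids.append(sid)
            members[sid] = [sid]
    families = sorted((sorted(members[c]) for c in centroids), key=lambda f: f[0])
    return ClusterSet(families=families, provenance="greedy_centroid")


def filter_paralogous_clusters(
    clusters: ClusterSet, specimen_of: Mapping[str, str]
) -> tuple[ClusterSet, ClusterSet, float]:
    """Remove families in which any specimen contributes >= 2 loci.

    Returns (kept, removed, fraction of sequences lost)."""
    kept, removed = [], []
    for fam in clusters.families:
        per_spec: dict[str, int] = {}
        for sid in fam:
            per_spec[specimen_of[sid]] = per_spec.get(specimen_of[sid], 0) + 1
        (removed if any(v >= 2 for v in per_spec.values()) else kept).append(list(fam))
    n_total = sum(len(f) for f in clusters.families)
    n_removed = sum(len(f) for f in removed)
    return (
        ClusterSet(families=kept, provenance=clusters.provenance),
        ClusterSet(families=removed, provenance=clusters.provenance),
        n_removed / n_total if n_total else 0.0,
    )


def clustering_efficiency(
    clusters: ClusterSet,
    truth: Mapping[str, object],
    min_species: int = 2,
    specimen_of: Mapping[str, str] | None = None,
) -> float:
    """Fraction of true homolog groups (with >= min_species species
    present) recovered exactly: all group members in one cluster that
    contains nothing else. Purity is part of the definition -- a group
    co-clustered with even one outside sequence counts as unrecovered."""
    if min_species < 2:
        raise ValueError("min_species must be >= 2")
    groups: dict[object, set[str]] = {}
    for sid, g in truth.items():
        groups.setdefault(g, set()).add(sid)
    eligible = []
    for g, members in groups.items():
        species = {specimen_of[m] for m in members} if specimen_of else members
        if len(species) >= min_species:
            eligible.append(frozenset(members))
    if not eligible:
        return float("nan")
    families = set(clusters.family_sets())
    return sum(1 for g in eligible if g in families) / len(eligible)
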
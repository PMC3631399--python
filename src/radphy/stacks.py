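"""Within-specimen locus assembly (a ustacks-style builder).

Reads are first grouped into *stacks* of strictly identical sequences; any
group of depth >= m becomes a stack and all remaining reads are *secondary*.
Stacks are then merged into putative loci by single linkage under a Hamming
mismatch cap M, so the two alleles of a heterozygous locus (~4 mismatches
at 5% over 85 bp) end up in the same locus. A frozen depth-weighted
majority consensus is called per locus before secondary reads are attached
to the nearest consensus within N mismatches (ties and larger distances
leave the read unattached; attachment only refines depth, never the
consensus).

Truth-based metrics compare putative loci to the known locus of each read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from ._seq import decode, encode_matrix, pairwise_hamming
from .read_sim import Read

__all__ = [
    "StackParams",
    "Stack",
    "PutativeLocus",
    "StacksMetrics",
    "build_stacks",
    "merge_stacks",
    "call_consensus",
    "attach_secondary",
    "stacks_metrics",
]


@dataclass(frozen=True)
class StackParams:
    """m: min depth to form a stack; M: max mismatches between stacks in a
    locus; n_mm: max mismatches to attach a secondary read."""

    m: int = 2
    M: int = 13
    n_mm: int = 9

    def __post_init__(self) -> None:
        if self.m < 1 or self.M < 0 or self.n_mm < 0:
            raise ValueError("require m >= 1, M >= 0, n_mm >= 0")


@dataclass
class Stack:
    specimen: str | None
    sequence: str
    reads: list[Read]

    @property
    def depth(self) -> int:
        return len(self.reads)


@dataclass
class PutativeLocus:
    specimen: str | None
    stacks: list[Stack]
    consensus: str = ""
    attached: list[Read] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return sum(s.depth for s in self.stacks) + len(self.attached)

    @property
    def truth_composition(self) -> set:
        """True locus ids among all reads assigned to this locus."""
        out = set()
        for stack in self.stacks:
            for read in stack.reads:
                if read.true_locus is not None:
                    out.add(read.true_locus)
        for read in self.attached:
            if read.true_locus is not None:
                out.add(read.true_locus)
        return out


@dataclass(frozen=True)
class StacksMetrics:
    recovery_rate: float
    split_rate: float
    paralog_merge_rate: float
    n_true_loci_sampled: int
    n_recovered: int
    n_putative_loci: int


def _as_reads(reads: Sequence[Read | str]) -> list[Read]:
    return [r if isinstance(r, Read) else Read(specimen=None, sequence=r) for r in reads]


def build_stacks(reads: Sequence[Read | str], m: int = 2) -> tuple[list[Stack], list[Read]]:
    """Group reads by exact sequence equality; groups of size >= m become
    stacks, everything else is returned as secondary reads."""
    if m < 1:
        raise ValueError("m must be >= 1")
    reads = _as_reads(reads)
    if reads:
        lengths = {len(r.sequence) for r in reads}
        if len(lengths) != 1:
            raise ValueError(f"reads have mixed lengths: {sorted(lengths)}")
    groups: dict[str, list[Read]] = {}
    for read in reads:
        groups.setdefault(read.sequence, []).append(read)
    stacks: list[Stack] = []
    secondary: list[Read] = []
    for seq, members in groups.items():
        if len(members) >= m:
            stacks.append(Stack(specimen=members[0].specimen, sequence=seq, reads=members))
        else:
            secondary.extend(members)
    return stacks, secondary


def merge_stacks(stacks: Sequence[Stack], M: int = 13) -> list[PutativeLocus]:
    """Single-linkage connected components of the Hamming<=M graph over
    stacks; each component becomes one putative locus with a frozen
    consensus."""
    stacks = list(stacks)
    if not stacks:
        return []
    mat = encode_matrix([s.sequence for s in stacks])
    dist = pairwise_hamming(mat)
    ds = DisjointSet(range(len(stacks)))
    ii, jj = np.nonzero(np.triu(dist <= M, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ds.merge(i, j)
    components = sorted((sorted(s) for s in ds.subsets()), key=lambda c: c[0])
    loci = []
    for comp in components:
        members = [stacks[i] for i in comp]
        locus = PutativeLocus(specimen=members[0].specimen, stacks=members)
        locus.consensus = call_consensus(locus)
        loci.append(locus)
    return loci


def call_consensus(locus: PutativeLocus | Sequence[Stack]) -> str:
    """Depth-weighted majority base per column over member stacks; ties
    break toward the alphabetically first base (A < C < G < T)."""
    stacks = locus.stacks if isinstance(locus, PutativeLocus) else list(locus)
    if not stacks:
        raise ValueError("consensus requires >= 1 member stack")
    mat = encode_matrix([s.sequence for s in stacks])
    weights = np.array([s.depth for s in stacks])
    counts = np.zeros((mat.shape[1], 4), dtype=np.int64)
    for row, w in zip(mat, weights):
        counts[np.arange(mat.shape[1]), row] += w
    return decode(np.argmax(counts, axis=1).astype(np.uint8))


def attach_secondary(
    loci: Sequence[PutativeLocus], secondary: Sequence[Read], n_mm: int = 9
) -> tuple[list[PutativeLocus], list[Read]]:
    """Attach each secondary read to the unique nearest consensus within
    ``n_mm`` mismatches; equidistant reads stay unattached. Consensus
    sequences are never updated. Returns (loci, unattached reads)."""
    loci = list(loci)
    secondary = _as_reads(secondary)
    if not loci or not secondary:
        return loci, list(secondary)
    cons = encode_matrix([l.consensus for l in loci])
    unattached: list[Read] = []
    sec_mat = encode_matrix([r.sequence for r in secondary])
    if sec_mat.shape[1] != cons.shape[1]:
        raise ValueError("secondary read length differs from consensus length")
    for read, row in zip(secondary, sec_mat):
        dists = (cons != row).sum(axis=1)
        best = int(dists.min())
        if best <= n_mm and int((dists == best).sum()) == 1:
            loci[int(np.argmin(dists))].attached.append(read)
        else:
            unattached.append(read)
    return loci, unattached


def stacks_metrics(loci: Sequence[PutativeLocus], reads: Sequence[Read]) -> StacksMetrics:
    """Truth-based evaluation of a clustering.

    recovery: fraction of true loci with >= 1 sampled read that are
    represented in >= 1 putative locus. split: fraction of recovered true
    loci whose reads span > 1 putative locus. paralog merge: fraction of
    putative loci containing reads from > 1 true locus.
    """
    sampled = {r.true_locus for r in reads if r.true_locus is not None}
    compositions = [l.truth_composition for l in loci]
    hits: dict = {}
    for comp in compositions:
        for key in comp:
            hits[key] = hits.get(key, 0) + 1
    recovered = {k for k in sampled if hits.get(k, 0) >= 1}
    split = {k for k in recovered if hits[k] > 1}
    n_multi = sum(1 for comp in compositions if len(comp) > 1)
    return StacksMetrics(
        recovery_rate=len(recovered) / len(sampled) if sampled else float("nan"),
        split_rate=len(split) / len(recovered) if recovered else float("nan"),
        paralog_merge_rate=n_multi / len(loci) if loci else float("nan"),
        n_true_loci_sampled=len(sampled),
        n_recovered=len(recovered),
        n_putative_loci=len(loci),
    )
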
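"""RAD read simulation and sequencing-design calculators.

Reads are simulated per locus -- a (restriction site, flank side) pair --
with Poisson(lambda) total depth, a fair choice among the alleles that carry
the locus, and a uniform per-base substitution error. Reads keep hidden
truth labels for evaluation; clustering never consumes them.

The design calculators implement the locus-level accounting used to plan
pooled libraries: mean coverage C = R / sum_i(2 * S_i) (each of the S_i
sites contributes two tags), and closed-form Poisson probabilities for the
chance that a locus is sequenced at least k times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._rng import substream
from ._seq import decode, encode, mutate
from .digestion import RadTag

__all__ = [
    "Read",
    "CoverageDesign",
    "simulate_reads",
    "coverage",
    "p_locus_sequenced",
    "max_pool_size",
]


@dataclass
class Read:
    """A simulated read plus hidden truth labels (evaluation only)."""

    specimen: str
    sequence: str
    true_site_id: tuple[int, int] | None = None
    true_side: str | None = None
    true_allele: str | None = None

    @property
    def true_locus(self) -> tuple[tuple[int, int], str] | None:
        if self.true_site_id is None:
            return None
        return (self.true_site_id, self.true_side)


@dataclass(frozen=True)
class CoverageDesign:
    R: int
    N: int
    S: tuple[int, ...]
    C: float


def simulate_reads(
    tags: Iterable[RadTag],
    mean_coverage: float,
    error_rate: float,
    seed: int,
) -> list[Read]:
    """Sample reads from a (possibly diploid) tag set.

    Tags are grouped by locus; each locus receives Poisson(mean_coverage)
    reads, each read copies one of the locus' alleles uniformly at random,
    and every base substitutes independently with probability
    ``error_rate`` to one of the three other bases.
    """
    if mean_coverage < 0:
        raise ValueError("mean coverage must be >= 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    loci: dict[tuple, list[RadTag]] = {}
    for tag in tags:
        loci.setdefault((tag.specimen, tag.site_id, tag.side), []).append(tag)
    if not loci:
        if mean_coverage > 0:
            warnings.warn("empty tag set: no reads simulated", stacklevel=2)
        return []
    rng = substream(seed, "reads")
    reads: list[Read] = []
    for key in sorted(loci):
        specimen, site_id, side = key
        alleles = sorted(loci[key], key=lambda t: t.allele)
        n = int(rng.poisson(mean_coverage))
        if n == 0:
            continue
        enc = np.vstack([encode(t.sequence) for t in alleles])
        picks = rng.integers(0, len(alleles), size=n)
        mat = mutate(enc[picks], error_rate, rng)
        for row, idx in zip(mat, picks):
            reads.append(
                Read(
                    specimen=specimen,
                    sequence=decode(row),
                    true_site_id=site_id,
                    true_side=side,
                    true_allele=alleles[idx].allele,
                )
            )
    return reads


def coverage(R: int, N: int, S: Sequence[int]) -> CoverageDesign:
    """Mean per-locus per-individual coverage for a pooled run:
    C = R / sum_i(2 * S_i)."""
    if R <= 0 or N <= 0:
        raise ValueError("R and N must be positive")
    S = tuple(int(s) for s in S)
    if len(S) != N:
        raise ValueError(f"expected {N} site counts, got {len(S)}")
    total_tags = 2 * sum(S)
    if total_tags <= 0:
        raise ValueError("total site count must be positive")
    return CoverageDesign(R=R, N=N, S=S, C=R / total_tags)


def p_locus_sequenced(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam): the chance a locus is sequenced at
    least ``k`` times at mean coverage ``lam``."""
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be >= 0")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def max_pool_size(R: int, target_C: float, mean_S: int) -> int:
    """Largest pool size N such that coverage(R, N, [mean_S]*N) >= target_C."""
    if R <= 0 or target_C <= 0 or mean_S <= 0:
        raise ValueError("all inputs must be positive")
    n = int(R // (2 * mean_S * target_C))
    if n < 1:
        raise ValueError(
            f"target coverage {target_C} unreachable even for a single individual "
            f"(max {R / (2 * mean_S):.2f})"
        )
    return n
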
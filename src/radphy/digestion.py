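"""Restriction digestion: site finding, RAD tag extraction, and the
site-conservation-versus-divergence relationship.

A RAD tag is the fixed-length flank on one side of a restriction site. The
5' flank is reverse-complemented at extraction so both tags read outward
from the cut site, as a sequencer would produce them; flanks shorter than
``tag_len`` (sites near a contig end) are dropped, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .genome_sim import HaploidGenome, p_distance

SBF1_MOTIF = "CCTGCAGG"

__all__ = [
    "SBF1_MOTIF",
    "RestrictionSite",
    "RadTag",
    "find_sites",
    "find_site_positions",
    "extract_tags",
    "conservation_curve",
    "expected_site_conservation",
]


@dataclass(frozen=True)
class RestrictionSite:
    """Exact motif occurrence; position is the 0-based leftmost base."""

    position: int
    anc_coord: int
    lineage: int

    @property
    def site_id(self) -> tuple[int, int]:
        return (self.anc_coord, self.lineage)


@dataclass(frozen=True)
class RadTag:
    specimen: str
    site_id: tuple[int, int]
    side: str  # "5prime" | "3prime"
    allele: str  # "a" | "b"
    sequence: str

    @property
    def locus_id(self) -> tuple[tuple[int, int], str]:
        """Tags from both alleles of one flank share a locus id."""
        return (self.site_id, self.side)


def _validate_motif(motif: str) -> None:
    if not motif:
        raise ValueError("motif must be non-empty")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")


def find_site_positions(sequence: str, motif: str = SBF1_MOTIF) -> list[int]:
    """All (possibly overlapping) occurrences, sorted by position. For a
    non-palindromic motif the reverse complement is searched too, since a
    restriction site is a double-stranded feature."""
    _validate_motif(motif)
    patterns = {motif}
    rc = revcomp(motif)
    if rc != motif:
        patterns.add(rc)
    positions: set[int] = set()
    for pat in patterns:
        start = sequence.find(pat)
        while start != -1:
            positions.add(start)
            start = sequence.find(pat, start + 1)
    return sorted(positions)


def find_sites(genome: HaploidGenome | str, motif: str = SBF1_MOTIF) -> list[RestrictionSite]:
    """Restriction sites of ``genome``, with truth labels taken from the
    coordinate map at the motif's leftmost base. A plain string is accepted
    and treated as a genome with identity coordinates."""
    if isinstance(genome, str):
        seq = genome
        coord = lambda p: (p, 0)  # noqa: E731
    else:
        seq = genome.sequence
        coord = genome.site_identity
    return [
        RestrictionSite(position=p, anc_coord=coord(p)[0], lineage=coord(p)[1])
        for p in find_site_positions(seq, motif)
    ]


def extract_tags(
    genome: HaploidGenome,
    sites: Sequence[RestrictionSite],
    tag_len: int,
    motif: str = SBF1_MOTIF,
    allele: str = "a",
) -> list[RadTag]:
    """Up to two fixed-length tags per site: the 5' flank (reverse
    complemented, reading away from the site) and the 3' flank."""
    if tag_len < 1:
        raise ValueError(f"tag_len must be >= 1, got {tag_len}")
    seq = genome.sequence
    mlen = len(motif)
    tags: list[RadTag] = []
    for site in sites:
        p = site.position
        if p - tag_len >= 0:
            tags.append(
                RadTag(
                    specimen=genome.taxon,
                    site_id=site.site_id,
                    side="5prime",
                    allele=allele,
                    sequence=revcomp(seq[p - tag_len : p]),
                )
            )
        if p + mlen + tag_len <= len(seq):
            tags.append(
                RadTag(
                    specimen=genome.taxon,
                    site_id=site.site_id,
                    side="3prime",
                    allele=allele,
                    sequence=seq[p + mlen : p + mlen + tag_len],
                )
            )
    return tags


def expected_site_conservation(p_per_lineage: float, motif_len: int = 8) -> float:
    """Independent-sites prediction for the fraction of sites conserved in
    both of two lineages, each mutating per site with probability ``p``:
    all ``2 * motif_len`` motif bases must stay intact."""
    return (1.0 - p_per_lineage) ** (2 * motif_len)


def conservation_curve(
    genomes: Mapping[str, HaploidGenome], motif: str = SBF1_MOTIF
) -> pd.DataFrame:
    """Per taxon pair: realized whole-genome p-distance and the fraction of
    the reference taxon's sites conserved (same ancestral coordinate and
    lineage tag present) in the other taxon.

    Columns: taxon_a, taxon_b, divergence, n_sites_ref, n_conserved,
    fraction. The first taxon of each sorted pair is the reference.
    """
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    lengths = {len(g) for g in genomes.values()}
    if len(lengths) != 1:
        raise ValueError("genomes must share a common ancestor (equal lengths)")
    site_ids = {
        taxon: {s.site_id for s in find_sites(g, motif)} for taxon, g in genomes.items()
    }
    rows = []
    for a, b in combinations(sorted(genomes), 2):
        ref = site_ids[a]
        conserved = len(ref & site_ids[b])
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "divergence": p_distance(genomes[a], genomes[b]),
                "n_sites_ref": len(ref),
                "n_conserved": conserved,
                "fraction": conserved / len(ref) if ref else float("nan"),
            }
        )
    return pd.DataFrame(rows)
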
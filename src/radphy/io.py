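"""File formats: FASTA/FASTQ, truth-map TSVs, hit tables, cluster tables,
supermatrix export (FASTA + relaxed PHYLIP) and newick trees.

Tag FASTA headers encode ``specimen|anc_coord|lineage|side|allele``; read
FASTA records are ``r{000001}`` with truth labels in a sidecar TSV, so the
clustering stages can be driven from files without ever reading truth.
Truth maps are written sparsely: positions where the ancestral coordinate
equals the position and the lineage tag is 0 (the overwhelming default in
an indel-free simulation) are omitted.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode
from .digestion import RadTag
from .genome_sim import DiploidGenome, HaploidGenome
from .homology import ClusterSet, PairHit
from .phylo import Supermatrix
from .read_sim import Read
from .stacks import PutativeLocus

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_diploid_fasta",
    "write_truth_map",
    "read_truth_map",
    "write_tags_fasta",
    "read_tags_fasta",
    "write_reads",
    "read_reads",
    "write_loci_tsv",
    "read_loci_tsv",
    "write_hits_tsv",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_supermatrix_fasta",
    "write_supermatrix_phylip",
    "write_conservation_tsv",
]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_diploid_fasta(genome: DiploidGenome, path: str | Path) -> None:
    write_fasta(
        [
            (f"{genome.specimen}_a", genome.haplotype_a.sequence),
            (f"{genome.specimen}_b", genome.haplotype_b.sequence),
        ],
        path,
    )


def write_truth_map(genome: HaploidGenome, path: str | Path) -> None:
    """Sparse TSV (position, ancestral_coord, lineage_tag); identity rows
    are omitted and reconstructed on read."""
    idx = np.nonzero(
        (genome.anc_coord != np.arange(len(genome))) | (genome.lineage != 0)
    )[0]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["#length", len(genome), ""])
        w.writerow(["position", "ancestral_coord", "lineage_tag"])
        for i in idx:
            w.writerow([int(i), int(genome.anc_coord[i]), int(genome.lineage[i])])


def read_truth_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    length = int(rows[0][1])
    anc = np.arange(length, dtype=np.int64)
    lin = np.zeros(length, dtype=np.int32)
    for pos, a, l in rows[2:]:
        anc[int(pos)] = int(a)
        lin[int(pos)] = int(l)
    return anc, lin


def load_haploid_genome(fasta_path: str | Path, truth_path: str | Path | None = None):
    """Rebuild HaploidGenome objects from a FASTA (+ optional truth map).
    Returns a dict keyed by record id."""
    out = {}
    for name, seq in read_fasta(fasta_path).items():
        L = len(seq)
        if truth_path is not None:
            anc, lin = read_truth_map(truth_path)
        else:
            anc, lin = np.arange(L, dtype=np.int64), np.zeros(L, dtype=np.int32)
        out[name] = HaploidGenome(taxon=name, seq=encode(seq), anc_coord=anc, lineage=lin)
    return out


def _tag_header(tag: RadTag) -> str:
    return f"{tag.specimen}|{tag.site_id[0]}|{tag.site_id[1]}|{tag.side}|{tag.allele}"


def write_tags_fasta(tags: Sequence[RadTag], path: str | Path) -> None:
    write_fasta(((_tag_header(t), t.sequence) for t in tags), path)


def read_tags_fasta(path: str | Path) -> list[RadTag]:
    tags = []
    for header, seq in read_fasta(path).items():
        specimen, anc, lin, side, allele = header.split("|")
        tags.append(
            RadTag(
                specimen=specimen,
                site_id=(int(anc), int(lin)),
                side=side,
                allele=allele,
                sequence=seq,
            )
        )
    return tags


def write_reads(
    reads: Sequence[Read], path: str | Path, fmt: str = "fasta", truth_path: str | Path | None = None
) -> None:
    """Write reads as FASTA or FASTQ (constant quality) plus an optional
    sidecar truth TSV keyed by read id."""
    records = []
    for k, read in enumerate(reads):
        rec = SeqRecord(Seq(read.sequence), id=f"r{k:06d}", description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(read.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)
    if truth_path is not None:
        with open(truth_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["read_id", "specimen", "anc_coord", "lineage", "side", "allele"])
            for k, read in enumerate(reads):
                sid = read.true_site_id or ("", "")
                w.writerow(
                    [f"r{k:06d}", read.specimen, sid[0], sid[1], read.true_side or "", read.true_allele or ""]
                )


def read_reads(path: str | Path, truth_path: str | Path | None = None, fmt: str = "fasta") -> list[Read]:
    truth: dict[str, tuple] = {}
    if truth_path is not None:
        with open(truth_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                site = (
                    (int(row["anc_coord"]), int(row["lineage"]))
                    if row["anc_coord"] != ""
                    else None
                )
                truth[row["read_id"]] = (
                    row["specimen"],
                    site,
                    row["side"] or None,
                    row["allele"] or None,
                )
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        specimen, site, side, allele = truth.get(rec.id, (None, None, None, None))
        reads.append(
            Read(
                specimen=specimen,
                sequence=str(rec.seq),
                true_site_id=site,
                true_side=side,
                true_allele=allele,
            )
        )
    return reads


def write_loci_tsv(loci: Mapping[str, Sequence[PutativeLocus]], path: str | Path) -> None:
    """One row per putative locus: specimen, locus_id, consensus, depth,
    n_stacks."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["specimen", "locus_id", "consensus", "depth", "n_stacks"])
        for specimen in sorted(loci):
            for k, locus in enumerate(loci[specimen]):
                w.writerow([specimen, f"{specimen}|L{k:05d}", locus.consensus, locus.depth, len(locus.stacks)])


def read_loci_tsv(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Returns (consensus sequences by locus id, specimen by locus id)."""
    seqs, spec = {}, {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            seqs[row["locus_id"]] = row["consensus"]
            spec[row["locus_id"]] = row["specimen"]
    return seqs, spec


def write_hits_tsv(hits: Sequence[PairHit], path: str | Path) -> None:
    """12-column tabular hit format (query, subject, %identity, alignment
    length, mismatches, gap opens, q.start, q.end, s.start, s.end, evalue,
    bitscore); coordinates 1-based as in the tabular convention."""
    import math

    from .homology import KA_K, _ka_lambda

    lam, k = _ka_lambda(), KA_K
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for h in hits:
            bitscore = (lam * h.score - math.log(k)) / math.log(2)
            w.writerow(
                [
                    h.query,
                    h.subject,
                    f"{100 * h.identity:.2f}",
                    h.aligned_columns,
                    h.mismatches,
                    h.gaps,
                    h.q_start + 1,
                    h.q_end,
                    h.s_start + 1,
                    h.s_end,
                    f"{h.evalue:.2e}",
                    f"{bitscore:.1f}",
                ]
            )


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["cluster_id", "member_id"])
        for k, fam in enumerate(clusters.families):
            for sid in fam:
                w.writerow([f"C{k:05d}", sid])


def read_clusters_tsv(path: str | Path, provenance: str = "single_linkage") -> ClusterSet:
    fams: dict[str, list[str]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            fams.setdefault(row["cluster_id"], []).append(row["member_id"])
    return ClusterSet(families=[fams[k] for k in sorted(fams)], provenance=provenance)


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    write_fasta(((t, sm.rows[t]) for t in sm.taxa), path)


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (name, two spaces, full row) for external ML tools."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.width}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_conservation_tsv(table, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
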
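"""End-to-end in-silico RAD-seq experiments.

:func:`run_experiment` drives the full chain -- synthetic genomes evolved
along a known tree, restriction digestion, diploid read simulation,
within-specimen locus assembly, cross-specimen homology clustering,
supermatrix construction and bootstrapped neighbor joining -- and scores
the result against the generating tree. All randomness flows from one
master seed through named substreams, so two runs with the same (config,
seed) produce identical reports.

:func:`simulate_locus_recovery` is the isolated locus-level benchmark: it
measures which fraction of independent diploid loci survive stack
formation and merging under chosen coverage, heterozygosity and error
conditions.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import io as rio
from ._rng import substream
from ._seq import decode, revcomp
from .digestion import SBF1_MOTIF, conservation_curve, extract_tags, find_sites, RadTag
from .genome_sim import (
    diploidize,
    evolve_along_tree,
    generate_ancestor,
    insert_duplications,
    simulate_tag_families,
)
from .homology import (
    ClusterParams,
    ClusterSet,
    PairHit,
    all_vs_all_hits,
    clustering_efficiency,
    filter_paralogous_clusters,
    greedy_centroid_cluster,
    single_linkage_cluster,
)
from .phylo import (
    align_family,
    bipartitions,
    bootstrap_support,
    build_supermatrix,
    informative_loci_per_node,
    rf_distance,
)
from .read_sim import Read, simulate_reads
from .stacks import (
    StackParams,
    attach_secondary,
    build_stacks,
    merge_stacks,
    stacks_metrics,
)
from .trees import deep_chain12, load_tree, validate_species_tree

logger = logging.getLogger("radphy")

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "PipelineError",
    "run_experiment",
    "short_read_mode",
    "compare_clusterers",
    "deep_family_comparison",
    "simulate_locus_recovery",
    "LocusRecoveryResult",
]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and a config echo."""

    def __init__(self, stage: str, message: str, config: "ExperimentConfig | None" = None):
        self.stage = stage
        cfg = f" [config: {config.summary()}]" if config is not None else ""
        super().__init__(f"{stage}: {message}{cfg}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment parameters; the defaults are the reference conditions of
    the simulated study (Sbf1 motif, 85-bp tags, 5% heterozygosity, 10x
    coverage, 1% error, stacks m=2/M=13/N=9, clustering i=r=0.35 at
    E<=1e-4 with 11-bp words, >=4 taxa per family, 100 bootstraps)."""

    tree: str = "ladder12"
    genome_length: int = 2_000_000
    gc: float = 0.5
    motif: str = SBF1_MOTIF
    tag_len: int = 85
    heterozygosity: float = 0.05
    mean_coverage: float = 10.0
    error_rate: float = 0.01
    m: int = 2
    M: int = 13
    n_mm: int = 9
    min_identity: float = 0.35
    min_overlap: float = 0.35
    evalue_cut: float = 1e-4
    word_size: int = 11
    min_taxa: int = 4
    bootstrap_reps: int = 100
    n_dup: int = 0
    dup_len: int = 1000
    dup_divergence: float = 0.15
    seed: int = 1

    def __post_init__(self) -> None:
        if self.tag_len < 1:
            raise ValueError("tag_len must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")

    def summary(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in dataclasses.asdict(self).items())

    def stack_params(self) -> StackParams:
        return StackParams(m=self.m, M=self.M, n_mm=self.n_mm)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            min_identity=self.min_identity,
            min_overlap=self.min_overlap,
            evalue_cut=self.evalue_cut,
            word_size=self.word_size,
        )

    @classmethod
    def from_ini(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        """Flat key-value INI ([radphy] section); CLI flags override."""
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keep m and M distinct
        with open(path) as fh:
            parser.read_file(fh)
        section = parser["radphy"] if parser.has_section("radphy") else parser["DEFAULT"]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in section:
                raw = section[f.name]
                # field types are strings under `from __future__ import annotations`
                tname = f.type if isinstance(f.type, str) else f.type.__name__
                if tname == "int":
                    kwargs[f.name] = int(raw)
                elif tname == "float":
                    kwargs[f.name] = float(raw)
                else:
                    kwargs[f.name] = raw
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_ini(self, path: str | Path) -> None:
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keep m and M distinct
        parser["radphy"] = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            parser.write(fh)


@dataclass
class ExperimentReport:
    config: dict
    conservation: pd.DataFrame
    stacks_per_specimen: dict[str, dict]
    stacks_pooled: dict
    pairwise_recovery: pd.DataFrame
    efficiency: pd.DataFrame
    fraction_tags_in_paralog_clusters: float
    n_consensus_sequences: int
    n_clusters: int
    n_informative_families: int
    gap_fraction: dict[str, float]
    tree_newick: str
    support_table: pd.DataFrame  # clade, size, support, truth_depth
    rf_to_truth: int
    informative_loci: pd.DataFrame  # clade, n_loci, truth_depth
    tag_len: int

    @property
    def min_support(self) -> float:
        return float(self.support_table["support"].min())

    def min_support_deep(self, depth_quantile: float = 0.5) -> float:
        """Minimum support among matched truth clades at or below the given
        depth quantile (deep half of the tree by default)."""
        t = self.support_table.dropna(subset=["truth_depth"])
        if t.empty:
            return float("nan")
        cut = t["truth_depth"].quantile(depth_quantile)
        return float(t.loc[t["truth_depth"] >= cut, "support"].min())

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "stacks_per_specimen": self.stacks_per_specimen,
            "stacks_pooled": self.stacks_pooled,
            "fraction_tags_in_paralog_clusters": self.fraction_tags_in_paralog_clusters,
            "n_consensus_sequences": self.n_consensus_sequences,
            "n_clusters": self.n_clusters,
            "n_informative_families": self.n_informative_families,
            "gap_fraction": self.gap_fraction,
            "tree_newick": self.tree_newick,
            "rf_to_truth": self.rf_to_truth,
            "min_support": self.min_support,
            "tag_len": self.tag_len,
            "conservation": self.conservation.to_dict(orient="records"),
            "pairwise_recovery": self.pairwise_recovery.to_dict(orient="records"),
            "efficiency": self.efficiency.to_dict(orient="records"),
            "support_table": json.loads(self.support_table.to_json(orient="records")),
            "informative_loci": json.loads(self.informative_loci.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.conservation.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        self.pairwise_recovery.to_csv(outdir / "pairwise_recovery.tsv", sep="\t", index=False)
        self.efficiency.to_csv(outdir / "efficiency.tsv", sep="\t", index=False)
        self.support_table.to_csv(outdir / "support.tsv", sep="\t", index=False)
        self.informative_loci.to_csv(outdir / "informative_loci.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"taxon": t, "gap_fraction": g} for t, g in sorted(self.gap_fraction.items())]
        ).to_csv(outdir / "gap_fractions.tsv", sep="\t", index=False)
        (outdir / "tree.nwk").write_text(self.tree_newick + "\n")


def _truth_depths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Depth (max root-to-... tip path below the node) of each internal
    clade of the rooted truth tree, keyed by leaf set."""
    out = {}
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out[leaves] = _node_depth(node)
    return out


def _node_depth(node) -> float:
    best = 0.0
    for leaf in node.leaf_iter():
        d = 0.0
        cur = leaf
        while cur is not node:
            d += cur.edge.length or 0.0
            cur = cur.parent_node
        best = max(best, d)
    return best


def _majority_truth(locus) -> tuple | None:
    """Most common true locus among a putative locus' reads (evaluation)."""
    counts: dict = {}
    for stack in locus.stacks:
        for read in stack.reads:
            if read.true_locus is not None:
                counts[read.true_locus] = counts.get(read.true_locus, 0) + 1
    for read in locus.attached:
        if read.true_locus is not None:
            counts[read.true_locus] = counts.get(read.true_locus, 0) + 1
    if not counts:
        return None
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _orient_families(
    clusters: ClusterSet, seqs: Mapping[str, str], hits: Sequence[PairHit]
) -> dict[str, str]:
    """Orient every member to the strand of its family's lexicographically
    smallest member, propagating hit strands over a spanning traversal."""
    strand: dict[tuple[str, str], str] = {}
    adj: dict[str, list[tuple[str, str]]] = {}
    for h in hits:
        adj.setdefault(h.query, []).append((h.subject, h.strand))
        adj.setdefault(h.subject, []).append((h.query, h.strand))
    oriented: dict[str, str] = {}
    for fam in clusters.families:
        root = min(fam)
        flip = {root: False}
        stack = [root]
        members = set(fam)
        while stack:
            cur = stack.pop()
            for nxt, s in adj.get(cur, ()):
                if nxt in members and nxt not in flip:
                    flip[nxt] = flip[cur] ^ (s == "-")
                    stack.append(nxt)
        for sid in fam:
            seq = seqs[sid]
            oriented[sid] = revcomp(seq) if flip.get(sid, False) else seq
    return oriented


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path | None = None,
    write_intermediates: bool = False,
) -> ExperimentReport:
    """Execute the full pipeline and score against the generating tree."""
    seed = config.seed
    try:
        tree = load_tree(config.tree)
        validate_species_tree(tree)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("species_tree", str(exc), config) from exc

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- genome simulation -------------------------------------------------
    logger.info("genome_sim: L=%d gc=%.2f seed=%d", config.genome_length, config.gc, seed)
    ancestor = generate_ancestor(config.genome_length, config.gc, seed)
    haploids = evolve_along_tree(ancestor, tree, seed)
    if config.n_dup > 0:
        haploids = {
            t: insert_duplications(g, config.n_dup, config.dup_len, config.dup_divergence, seed)
            for t, g in sorted(haploids.items())
        }
    diploids = {
        t: diploidize(g, config.heterozygosity, seed) for t, g in sorted(haploids.items())
    }

    # --- digestion ---------------------------------------------------------
    conservation = conservation_curve(haploids, config.motif)
    all_tags: list[RadTag] = []
    for t in sorted(diploids):
        dip = diploids[t]
        for hap, allele in ((dip.haplotype_a, "a"), (dip.haplotype_b, "b")):
            sites = find_sites(hap, config.motif)
            all_tags.extend(
                extract_tags(hap, sites, config.tag_len, motif=config.motif, allele=allele)
            )
    logger.info("digestion: %d tags across %d specimens", len(all_tags), len(diploids))
    if not all_tags:
        raise PipelineError("digestion", "no restriction sites found", config)

    # --- read simulation ---------------------------------------------------
    reads = simulate_reads(all_tags, config.mean_coverage, config.error_rate, seed)
    logger.info("read_sim: %d reads", len(reads))
    if not reads:
        raise PipelineError("stacks", "no reads to assemble (mean coverage 0?)", config)

    # --- within-specimen locus assembly ------------------------------------
    params = config.stack_params()
    by_spec: dict[str, list[Read]] = {}
    for r in reads:
        by_spec.setdefault(r.specimen, []).append(r)
    loci_by_spec = {}
    metrics_by_spec = {}
    for t in sorted(by_spec):
        stacks, secondary = build_stacks(by_spec[t], params.m)
        loci = merge_stacks(stacks, params.M)
        loci, _ = attach_secondary(loci, secondary, params.n_mm)
        loci_by_spec[t] = loci
        metrics_by_spec[t] = stacks_metrics(loci, by_spec[t])
    pooled = _pool_metrics(metrics_by_spec)
    logger.info("stacks: %s", pooled)

    # --- consensus sequences with evaluation labels -------------------------
    seqs: dict[str, str] = {}
    specimen_of: dict[str, str] = {}
    truth_of: dict[str, tuple] = {}
    for t in sorted(loci_by_spec):
        for k, locus in enumerate(loci_by_spec[t]):
            sid = f"{t}|L{k:05d}"
            seqs[sid] = locus.consensus
            specimen_of[sid] = t
            maj = _majority_truth(locus)
            if maj is not None:
                truth_of[sid] = maj

    # --- homology clustering ------------------------------------------------
    cparams = config.cluster_params()
    try:
        hits = all_vs_all_hits(seqs, cparams)
    except ValueError as exc:
        raise PipelineError("homology", str(exc), config) from exc
    clusters = single_linkage_cluster(
        list(seqs), hits, cparams.min_identity, cparams.min_overlap
    )
    kept, removed, frac_removed = filter_paralogous_clusters(clusters, specimen_of)
    truth_groups = {sid: (truth_of[sid][0], truth_of[sid][1]) for sid in truth_of}
    greedy = greedy_centroid_cluster(seqs, cparams.min_identity)
    efficiency = pd.DataFrame(
        [
            {
                "method": method,
                "min_species": ms,
                "efficiency": clustering_efficiency(cs, truth_groups, ms, specimen_of),
            }
            for ms in (4, 6, 9)
            for method, cs in (("single_linkage", clusters), ("greedy_centroid", greedy))
        ]
    )
    pairwise = _pairwise_recovery(clusters, removed, truth_of, specimen_of)
    logger.info(
        "homology: %d clusters (%d kept after paralog filter, %.1f%% of tags removed)",
        len(clusters.families), len(kept.families), 100 * frac_removed,
    )

    # --- supermatrix & tree -------------------------------------------------
    oriented = _orient_families(kept, seqs, hits)
    families = [
        align_family(f"C{k:05d}", {specimen_of[sid]: oriented[sid] for sid in fam})
        for k, fam in enumerate(kept.families)
        if len(fam) >= 2
    ]
    try:
        sm = build_supermatrix(families, config.min_taxa)
        supported = bootstrap_support(sm, config.bootstrap_reps, seed)
    except ValueError as exc:
        raise PipelineError("phylo", str(exc), config) from exc

    depths = _truth_depths(tree)
    truth_bips = bipartitions(tree)
    all_taxa = frozenset(sm.taxa)

    def clade_depth(bip: frozenset) -> float | None:
        if bip in depths:
            return depths[bip]
        comp = frozenset(all_taxa - bip)
        return depths.get(comp)

    support_table = pd.DataFrame(
        [
            {
                "clade": ",".join(sorted(bip)),
                "size": len(bip),
                "support": s,
                "truth_depth": clade_depth(bip),
                "in_truth": bip in truth_bips,
            }
            for bip, s in sorted(supported.supports.items(), key=lambda kv: sorted(kv[0]))
        ]
    )
    rf = rf_distance(supported.tree, tree)
    informative = informative_loci_per_node(families, tree)
    informative_df = pd.DataFrame(
        [
            {
                "clade": ",".join(sorted(leaves)),
                "n_loci": n,
                "truth_depth": depths.get(leaves),
            }
            for leaves, n in sorted(informative.items(), key=lambda kv: sorted(kv[0]))
        ]
    )

    report = ExperimentReport(
        config=dataclasses.asdict(config),
        conservation=conservation,
        stacks_per_specimen={t: dataclasses.asdict(m) for t, m in metrics_by_spec.items()},
        stacks_pooled=pooled,
        pairwise_recovery=pairwise,
        efficiency=efficiency,
        fraction_tags_in_paralog_clusters=frac_removed,
        n_consensus_sequences=len(seqs),
        n_clusters=len(clusters.families),
        n_informative_families=len(sm.spans),
        gap_fraction=sm.gap_fraction,
        tree_newick=supported.newick(),
        support_table=support_table,
        rf_to_truth=rf,
        informative_loci=informative_df,
        tag_len=config.tag_len,
    )

    if out is not None:
        report.write(out)
        rio.write_supermatrix_fasta(sm, out / "supermatrix.fasta")
        rio.write_supermatrix_phylip(sm, out / "supermatrix.phy")
        tree.write(path=str(out / "true_tree.nwk"), schema="newick")
        if write_intermediates:
            _write_intermediates(out, diploids, haploids, all_tags, reads, loci_by_spec, hits, clusters)
    return report


def _write_intermediates(out, diploids, haploids, tags, reads, loci_by_spec, hits, clusters):
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    for t in sorted(diploids):
        rio.write_diploid_fasta(diploids[t], gdir / f"{t}.fasta")
        rio.write_truth_map(haploids[t], gdir / f"{t}.truth.tsv")
    rio.write_tags_fasta(tags, out / "tags.fasta")
    rio.write_reads(reads, out / "reads.fasta", truth_path=out / "reads.truth.tsv")
    rio.write_loci_tsv(loci_by_spec, out / "loci.tsv")
    rio.write_hits_tsv(hits, out / "hits.tsv")
    rio.write_clusters_tsv(clusters, out / "clusters.tsv")


def _pool_metrics(per_spec: dict) -> dict:
    n_sampled = sum(m.n_true_loci_sampled for m in per_spec.values())
    n_recovered = sum(m.n_recovered for m in per_spec.values())
    n_loci = sum(m.n_putative_loci for m in per_spec.values())
    split = sum(m.split_rate * m.n_recovered for m in per_spec.values())
    paralog = sum(m.paralog_merge_rate * m.n_putative_loci for m in per_spec.values())
    return {
        "recovery_rate": n_recovered / n_sampled if n_sampled else float("nan"),
        "split_rate": split / n_recovered if n_recovered else float("nan"),
        "paralog_merge_rate": paralog / n_loci if n_loci else float("nan"),
        "n_true_loci_sampled": n_sampled,
        "n_recovered": n_recovered,
        "n_putative_loci": n_loci,
    }


def _pairwise_recovery(
    clusters: ClusterSet,
    removed: ClusterSet,
    truth_of: Mapping[str, tuple],
    specimen_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per specimen pair: how many true ortholog pairs exist among the
    consensus sequences, which fraction sit in one cluster, and which
    fraction of those clusters contain putative paralogs."""
    cluster_of = clusters.as_mapping()
    removed_sets = set()
    for fam in removed.families:
        for sid in fam:
            removed_sets.add(sid)
    by_truth: dict[tuple, dict[str, list[str]]] = {}
    for sid, key in truth_of.items():
        by_truth.setdefault(key, {}).setdefault(specimen_of[sid], []).append(sid)
    specimens = sorted({s for s in specimen_of.values()})
    rows = []
    for i, a in enumerate(specimens):
        for b in specimens[i + 1 :]:
            n_orth = retrieved = in_paralog = 0
            for key, by_spec in by_truth.items():
                if a in by_spec and b in by_spec and len(by_spec[a]) == 1 and len(by_spec[b]) == 1:
                    n_orth += 1
                    sa, sb = by_spec[a][0], by_spec[b][0]
                    if cluster_of[sa] == cluster_of[sb]:
                        retrieved += 1
                        if sa in removed_sets:
                            in_paralog += 1
            rows.append(
                {
                    "specimen_a": a,
                    "specimen_b": b,
                    "n_orthologous": n_orth,
                    "retrieved_fraction": retrieved / n_orth if n_orth else float("nan"),
                    "in_paralog_cluster_fraction": in_paralog / retrieved if retrieved else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def short_read_mode(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentReport:
    """The identical pipeline at 35-bp tags (51-bp reads after barcode and
    motif); the report's support table allows comparison of deep-node
    supports against an 85-bp run."""
    return run_experiment(replace(config, tag_len=35), outdir=outdir)


def compare_clusterers(
    seqs: Mapping[str, str],
    truth: Mapping[str, object],
    specimen_of: Mapping[str, str],
    identity_thresholds: Sequence[float] = (0.35, 0.9),
    min_species_list: Sequence[int] = (4, 6, 9),
    min_overlap: float = 0.35,
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Efficiency grid: single-linkage vs greedy-centroid clustering over
    identity thresholds and minimum-species strata, on the same input."""
    params = params or ClusterParams(min_overlap=min_overlap)
    hits = all_vs_all_hits(seqs, params)
    rows = []
    for ident in identity_thresholds:
        sl = single_linkage_cluster(list(seqs), hits, ident, min_overlap)
        greedy = greedy_centroid_cluster(seqs, ident)
        for ms in min_species_list:
            for method, cs in (("single_linkage", sl), ("greedy_centroid", greedy)):
                rows.append(
                    {
                        "method": method,
                        "identity": ident,
                        "min_overlap": min_overlap if method == "single_linkage" else float("nan"),
                        "min_species": ms,
                        "efficiency": clustering_efficiency(cs, truth, ms, specimen_of),
                    }
                )
    return pd.DataFrame(rows)


def deep_family_comparison(
    n_families: int = 30,
    tag_len: int = 85,
    seed: int = 1,
    identity_thresholds: Sequence[float] = (0.35, 0.9),
    min_species_list: Sequence[int] = (4, 6, 9),
) -> pd.DataFrame:
    """Clusterer comparison on deep synthetic homolog families evolved
    along the deep_chain12 tree (adjacent tips alignable, deepest pairs
    below the permissive identity threshold)."""
    seqs, truth, specimen_of = simulate_tag_families(deep_chain12(), n_families, tag_len, seed)
    return compare_clusterers(
        seqs, truth, specimen_of, identity_thresholds, min_species_list
    )


@dataclass(frozen=True)
class LocusRecoveryResult:
    n_loci: int
    n_sampled: int
    n_recovered: int
    n_split: int
    recovery_rate: float
    split_rate: float
    consensus_exact_fraction: float | None

    @property
    def recovery_percent(self) -> float:
        return 100.0 * self.recovery_rate


def simulate_locus_recovery(
    n_loci: int,
    tag_len: int = 85,
    heterozygosity: float = 0.05,
    mean_coverage: float = 10.0,
    error_rate: float = 0.01,
    params: StackParams | None = None,
    seed: int = 1,
    motif_len: int = 8,
) -> LocusRecoveryResult:
    """Locus-level stack-formation benchmark on independent diploid loci.

    Each locus is a tag anchored at a ``motif_len``-bp recognition site.
    The second allele mutates per site with probability ``heterozygosity``
    over both tag and site; when the site is destroyed in the second allele
    (probability 1-(1-h)^motif_len) the locus is hemizygous and all its
    reads come from the first allele. Total reads per locus are
    Poisson(mean_coverage), split evenly between the alleles that carry the
    locus, with uniform per-base errors. A locus is recovered when at least
    one putative locus contains its reads after stack formation (depth >=
    m) and single-linkage merging (Hamming <= M).
    """
    params = params or StackParams()
    rng = substream(seed, "locus-recovery")
    alleles_a = rng.integers(0, 4, size=(n_loci, tag_len), dtype=np.uint8)
    from ._seq import mutate

    alleles_b = mutate(alleles_a, heterozygosity, rng)
    # does the second allele keep its recognition site intact?
    b_has_site = rng.random(n_loci) >= 1.0 - (1.0 - heterozygosity) ** motif_len
    tags: list[RadTag] = []
    for i in range(n_loci):
        tags.append(RadTag("sim", (i, 0), "3prime", "a", decode(alleles_a[i])))
        if b_has_site[i]:
            tags.append(RadTag("sim", (i, 0), "3prime", "b", decode(alleles_b[i])))
    reads = simulate_reads(tags, mean_coverage, error_rate, seed)
    by_locus: dict[int, list[Read]] = {}
    for r in reads:
        by_locus.setdefault(r.true_site_id[0], []).append(r)
    n_sampled = len(by_locus)
    n_recovered = n_split = 0
    check_consensus = heterozygosity == 0 and error_rate == 0
    n_consensus_exact = 0
    for i, locus_reads in by_locus.items():
        stacks, secondary = build_stacks(locus_reads, params.m)
        loci = merge_stacks(stacks, params.M)
        loci, _ = attach_secondary(loci, secondary, params.n_mm)
        if loci:
            n_recovered += 1
            if len(loci) > 1:
                n_split += 1
            if check_consensus and all(
                l.consensus == decode(alleles_a[i]) for l in loci
            ):
                n_consensus_exact += 1
    return LocusRecoveryResult(
        n_loci=n_loci,
        n_sampled=n_sampled,
        n_recovered=n_recovered,
        n_split=n_split,
        recovery_rate=n_recovered / n_sampled if n_sampled else float("nan"),
        split_rate=n_split / n_recovered if n_recovered else float("nan"),
        consensus_exact_fraction=(n_consensus_exact / n_recovered if n_recovered else None)
        if check_consensus
        else None,
    )
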
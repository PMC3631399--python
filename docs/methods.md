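# Methods

## Mutation model and positional truth

Genomes evolve by substitution only. A branch of length *d* expected
substitutions/site is applied as one Bernoulli pass: each site changes
with probability p_sub(d) = (3/4)(1 − e^(−4d/3)) — the Jukes–Cantor
probability that a site differs after *d*, which folds multiple hits and
back-mutation into a single draw — and a changed site moves to one of the
three other bases uniformly. Because the expected *observed* distance
along a path is what JC predicts for the summed path length, branch
lengths are additive by construction; the oracle tests check realized
p-distances against (3/4)(1 − e^(−4D/3)) for paths D.

With no indels, position *i* in every descendant is homologous to
position *i* in the ancestor. The truth map (ancestral coordinate +
duplication-lineage tag per position) is therefore carried by reference
and only copied when `insert_duplications` writes a duplicated window.
Duplications *overwrite* a random non-overlapping destination window of
equal length rather than inserting, keeping genome length constant and
the positional truth exact; the copy keeps its source's ancestral
coordinates with a fresh lineage tag, which is what lets downstream
evaluation label tag pairs orthologous (same coordinate and lineage) or
paralogous (same coordinate, different lineage).

Heterozygosity is a derived second haplotype: each site of the first
mutates independently with probability *h* (default 0.05, an upper bound
for natural polymorphism). Note the second allele is a *derived copy* of
the first, not an equidistant draw from a population — adequate for
clustering and recovery questions, but it makes the first allele the
"tree lineage" (see the noise analysis below). Crucially the recognition
site itself mutates too, so at h = 0.05 about 1 − 0.95⁸ ≈ 34% of a
genome's loci are hemizygous (present on one allele); this presence/
absence polymorphism is part of the model, not an artifact.

## Reference conditions

Defaults in `ExperimentConfig` are the reference study conditions: Sbf1
motif `CCTGCAGG`, 85-bp tags (35-bp in short-read mode), h = 0.05, mean
coverage λ = 10 per locus, error e = 0.01/base uniform over the three
alternative bases, stack parameters m = 2 / M = 13 / N = 9, clustering
thresholds identity = overlap = 0.35 at E ≤ 10⁻⁴ with 11-bp seed words,
families kept at ≥ 4 distinct taxa, 100 bootstrap replicates. Coverage is
per tag locus; reads split fairly among the alleles that carry the locus.

Under these conditions ~88.3% of sampled diploid loci survive stack
formation and merging. The decomposition: an 85-bp read is error-free
with probability 0.99⁸⁵ ≈ 0.43; a two-allele locus needs ≥ 2 error-free
reads of the *same* allele out of Poisson(10) total, giving ≈ 86%; the
~34% hemizygous loci concentrate all 10× on one allele and recover at
≈ 93%; the mixture lands at ≈ 88%. `simulate_locus_recovery` reproduces
this (88.5% at 20,000 loci, seed 3), and with h = e = 0 it matches the
closed form P(Poisson(10) ≥ 2) = 1 − 11e⁻¹⁰ with exact consensus
sequences and zero splits.

## Locus assembly

Stacks are exact-equality read groups of depth ≥ m; merging is
single-linkage (union–find) over the Hamming ≤ M graph, chosen because it
reproduces the intended behaviour that two alleles ~4 mismatches apart
(5% of 85 bp) always land in one locus while unrelated tags (~64
mismatches apart) never do. Consensus is the depth-weighted majority per
column, ties broken A < C < G < T, computed before secondary attachment
and frozen; secondary reads attach to the unique nearest consensus within
N mismatches (ties unattached) and only refine depth. All comparisons
require equal read lengths.

## Homology clustering

Candidate pairs must share an exact `word_size`-mer on either strand with
seed entropy ≥ 1.5 bits/base (a simple low-complexity filter). Candidates
get a full Smith–Waterman local alignment (match +1, mismatch −2, gap
open −5, extend −2) — at ≤ 85 bp the full DP is cheap, so no banded
extension is needed — and a hit is kept when the ungapped Karlin–Altschul
E-value K·m·n·e^(−λS) (λ ≈ 1.33 solved from the scoring scheme, K =
0.621) is at most the cutoff. Identity is matches/aligned-columns,
overlap is aligned-columns/max(sequence lengths) — the conservative
denominator. Single-linkage families are connected components of the
qualifying-hit graph; ids without an edge are singletons; the partition
is invariant to hit order.

The greedy-centroid baseline processes sequences in seed order and joins
the first centroid whose *global identity over the entire length* reaches
the threshold. For equal-length, cut-site-anchored tags from an
indel-free model, the optimal global alignment is ungapped, so identity
is the matching-position fraction (best of both strands); a gapped
aligner would score two random 85-mers at ~0.40–0.47 "identity" by
fishing for chance matches and make any permissive threshold degenerate.
Unequal lengths fall back to a stiff-gap Needleman–Wunsch normalized by
the longer length.

Paralog filtering removes clusters in which any specimen contributes ≥ 2
loci. Clustering efficiency over a minimum-species stratum counts a true
ortholog group as recovered only if all its members sit in one cluster
containing nothing else — purity included, so one absorbed paralog voids
the group.

The `deep_chain12` preset that stresses this comparison is a
non-ultrametric caterpillar (pendant 0.05, backbone 0.08
substitutions/site): adjacent tips at ~84% identity share an 11-mer run
with probability ~0.94 (run-length statistics of Bernoulli matches — the
binding constraint on chaining), while the most distant tips sit at ~48%
identity over a 0.9-substitutions/site path, far below any stringent
threshold. Single linkage walks the chain; the greedy method fragments
deep families and, at permissive thresholds, occasionally absorbs wrong
members whose by-chance identity crosses 0.35 — the two failure modes the
comparison is meant to expose.

## Supermatrix and tree

Families are positionally aligned (indel-free, site-anchored; shorter
rows right-padded), concatenated in cluster-id order with gap fill, and
reduced to pairwise distances by pairwise deletion with an optional JC
correction (p ≥ 0.75 is reported as undefined, and a taxon pair sharing
no ungapped columns aborts the run rather than imputing a distance).
Neighbor joining breaks Q-matrix ties by taxon label order and clamps
negative branch estimates to zero; it recovers additive matrices exactly
(oracle-tested against brute-force path distances and an independent NJ
implementation). Bootstrap resamples alignment columns; an internal
edge's support is the percentage of replicates containing the same
bipartition. Maximum-likelihood inference is deliberately out of scope;
the supermatrix is exported in FASTA and relaxed PHYLIP for external ML
tools.

## The ladder12 preset and the limits of the 2-Mb scale

`ladder12` is an ultrametric 12-taxon caterpillar with node depths linear
from 0.02 to 0.10 substitutions/site (pairwise divergences 0.04–0.20,
site conservation ~73% down to ~21%). The depth range is deliberately
much shallower than the deepest divergences a full-genome study spans
(pairwise ~1.3 at fourfold-degenerate sites): in a fully neutral genome,
a site survives a pairwise path D with probability ≈ (1 − p_sub(D/2))¹⁶,
which at D = 1.3 is ~10⁻⁴ — a 2-Mb genome (~30 Sbf1 sites) would retain
essentially zero shared sites and no pair of deep taxa would have a
defined distance. Real genomes reach deep *fourfold-site* divergence
while genome-wide divergence stays far lower; a neutral simulator has no
such separation, so the preset scales divergence down with the genome.
The deep-conservation regime itself (down to a few percent) is exercised
separately by the conservation-curve oracle at p up to 0.2 per lineage.

Even so, the 2-Mb scale cannot deliver a fully supported tree, and it is
worth being precise about why. The consensus of a heterozygous locus
follows whichever allele stacked deeper, so per locus and per taxon it
carries the derived allele's ~h·L private mutations with probability
~1/2: a per-locus, per-taxon distance noise with standard deviation
~h/2 ≈ 0.025 (measured ~0.03–0.06 after JC amplification). With at most
~60 loci at 2 Mb, pairwise distances carry SE ≥ 0.054/√60 ≈ 0.007, so
≥ 95% bootstrap support needs internal edges ≳ 0.02 — but ten caterpillar
edges of 0.02 put the root at ≥ 0.22, where deep pairs retain ~3% of
sites and distances become undefined. The two requirements cannot be met
simultaneously by any 12-taxon ladder at this genome size; solving
z = e·√(N·e^(−160e))/σ ≥ 3 for the optimal edge length e* ≈ 0.0125 shows
a ~40–60 Mb genome (~600–900 sites) is where full support becomes
reachable. The end-to-end run therefore reports an honest partial result
at 2 Mb (Robinson–Foulds 4, supports 47–97% at seed 1) while every
component is verified by oracle tests at scales where the expected signal
is unambiguous; `run_experiment` accepts any `genome_length` for users
with more patience.

## What the generator does and does not emulate

It emulates: site gain/loss with divergence, flank decay, heterozygous
and hemizygous loci, Poisson coverage, uniform sequencing error, and
(optionally) recent segmental duplication. It does not emulate: indels,
rate variation among sites or lineages, GC heterogeneity, recombination,
incomplete lineage sorting, PCR duplicates, coverage bias, partial
digestion, or population-level allele sharing. Passing tests therefore
demonstrate the pipeline's behaviour under a clean substitution-only
model; on real data, indels and rate variation will degrade positional
alignment and site conservation further.

## Numerics and determinism

All randomness flows from one master seed through named substreams
(`ancestor`, `evolve`, `diploidize:<taxon>`, `reads`, `bootstrap`, ...),
so stages are independently reproducible and identical (config, seed)
runs produce byte-identical reports. Ties are broken deterministically
everywhere (consensus A < C < G < T; NJ by taxon label; secondary-read
ties unattached). Degenerate inputs fail loudly: empty tag sets warn and
return nothing, a coverage of zero aborts the pipeline at the stacks
stage, taxon pairs without shared columns abort tree building.
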
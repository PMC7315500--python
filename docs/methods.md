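# Methods

This note documents the models, numerical choices and limitations behind
`mirisonet`, in the spirit of a statistical-software methods appendix.

## Target scoring model

A duplex aligns a miRNA (positions 1…k from its 5′ end) antiparallel to a
transcript window; position 1 pairs the 3′-most window base. Column
penalties are 0 for Watson–Crick pairs, 0.5 for G:U wobbles (either
orientation — wobble pairing is symmetric), and 1 for mismatches, target
bulges and target gaps, doubled when the column's miRNA position lies in
[2, 13] inclusive. A *bulge* is an extra unpaired target nucleotide between
the partners of two adjacent miRNA positions; a *gap* is a miRNA base with no
target partner. At most one bulge or gap is allowed per alignment. A bulge
column has no miRNA position of its own; it takes the adjacent 5′-side miRNA
position for the doubling test — a deterministic rule, fixed here because the
alternatives (3′-side, maximum) are equally defensible and untestable from
the decision rule alone. Sites with score ≤ 3.0 (inclusive) are retained.

Search is exhaustive, not heuristic: for each miRNA × transcript pair, every
window is evaluated under the gapless alignment plus every single-bulge
(interior positions 1…k−1) and single-gap (positions 1…k, terminal gaps
included) alignment; per window the minimum-score alignment is kept, and
overlapping surviving windows of one miRNA are reduced greedily
best-score-first (ties to the leftmost). The scan is vectorised: all variant
scores decompose into prefix/suffix sums of one k × L position-penalty
matrix, giving O(k·L) work per variant and O(k²·L) overall — exact and fast
at the scales this package targets (tens of miRNAs × thousands of short
transcripts). Equivalence with a naive full enumeration is property-tested
on ≥1000 random instances.

No minimum pairing at position 1, no 3′-compensation bonus and no
thermodynamic (ΔG) term are applied; cutoff and indel allowance are exposed
as parameters.

## Differential expression

The decision rule is BH-adjusted FDR < 0.05 together with |log2FC| > 1, both
strict. The count test is a negative-binomial exact-style test: counts are
scaled to the geometric-mean library size, a common dispersion φ is
estimated by the method of moments (mean of positive per-feature
(s² − m)/m² values, clipped to [0, 10]), and the two group sums — each NB
with mean proportional to group size and dispersion φ/n — are compared
conditionally on their total, summing the probability of all splits no more
likely than the observed one. log2FC is computed on per-million-normalised
group means with pseudo-count 1 (pseudo-count 0 is allowed and yields ±inf
on empty groups). This reproduces the published decision rule without
cloning a specific DE package's internals; the test function is pluggable.
With singleton groups the dispersion falls back to whatever replicated
groups provide, or to Poisson (φ = 0) when none exist.

## Normalisation and filtering

Small-RNA TPM is counts-per-million over mapped miRNA reads: mature miRNAs
have essentially uniform effective length, so no length term is applied;
columns sum to 10⁶ exactly. Isoform FPKM is count / (length/10³) /
(libsize/10⁶) with library size defaulting to the column sum. The
pre-network filter retains features with mean FPKM > 0.1 and C.V. > 2 (both
strict; features sitting exactly on a threshold are dropped). The C.V. is
computed across per-tissue mean profiles with the sample (n−1) standard
deviation: the filter targets cross-tissue variability, not replicate noise.
Both choices are parameters.

## Network construction

Unsigned adjacency |cor|^β with β = 6 by default (the community default for
unsigned networks); an optional chooser picks the smallest β whose log-log
degree-distribution fit reaches R² ≥ 0.8. TOM follows the standard formula
with unit diagonal. Module detection is a deliberate simplification of the
dynamic hybrid tree cut: average-linkage clustering on 1 − TOM, a static cut
at height 0.99, a minimum module size (600 at genome scale; tests and the
synthetic demos use 10–50, matching their feature counts), then iterative
merging of the closest module pair while eigengene dissimilarity
(1 − cor) < 0.5, recomputing eigengenes after each merge. The PAM-like
reassignment stages of the full dynamic cut are intentionally out of scope;
on block-structured data the simplified procedure recovers planted
partitions exactly, which is what the validation suite requires. Surviving
modules take standard colour names in decreasing size order; unassigned
features are grey.

Module eigengenes are PC1 across samples of the z-scored member matrix,
sign-oriented so the mean member correlation is positive. Module–trait
correlations use one-hot tissue indicators with t-distribution p-values
(n − 2 df), cross-checked against a permutation oracle in tests. kME is the
Pearson correlation of a feature with a module eigengene; hubs are the top
min(150, module size) members by own-module kME, ties broken by feature id.

## Integration and divergence statistics

miRNA–target correlations are computed over per-tissue means, because miRNA
and mRNA libraries come from different physical samples and tissue is the
only shared axis. The six correlation bins partition [−1, 1] totally:
negative bins close on their lower bound, 0 belongs to weak-positive —
boundary membership must be fixed somewhere, and this is the documented
choice. Zero-variance profiles are excluded and logged.

The DEMTG and hub-enrichment tests are 2×2 χ² with Yates continuity
correction (Fisher's exact available via flag). For hub enrichment the
non-hub margin is derived by subtracting hubs from the module so no isoform
is double-counted. χ² with Yates agrees closely with Fisher for moderate
p-values but can differ by more than 10 % in relative terms deep in the
tails; significance calls agree.

Homolog categories follow strict precedence I > III > II: any pair of
isoforms hitting different genes in the other species makes the gene
category I regardless of other evidence, because cross-gene divergence is
the strongest signal. Genes with fewer than two hit-bearing isoforms are
excluded.

Term enrichment uses the central hypergeometric upper tail, or — when bias
weights such as transcript length are supplied — the Wallenius non-central
hypergeometric with odds = (mean weight in term)/(mean weight outside),
evaluated through the standard integral representation by adaptive
quadrature (absolute tolerance 10⁻¹², exact central special case at odds 1).
GO-DAG propagation is not implemented; term maps are taken as flat,
already-propagated annotations.

## Synthetic data: what it emulates, and what it does not

The generator plants, per seed: (a) isoform families sharing backbone
segments and differing by inclusion of one skippable CDS segment, so some
miRNAs target only a subset of a gene's isoforms; (b) target sites that are
exact reverse complements of their miRNA with optional distortions (G:U,
mismatch, single bulge/gap) whose expected score is computed independently
by the penalty arithmetic at planting time and later compared against the
scanner; (c) block-structured expression — each module high in one tissue —
with negative-binomial counts (dispersion 0.05 by default, in the range
typical of replicate RNA-seq); (d) miRNA profiles suppressed in exactly the
tissues where their targets are expressed, at a configurable repression
strength (0.9 by default); (e) a flat "housekeeping" background
(≈35 % of genes at a stable mean) whose role is to keep per-sample library
sizes realistic — without it, tissues hosting no module would have tiny
libraries and compositional normalisation would flatten every profile.
These background isoforms are exactly the universally-expressed class the
C.V. filter is designed to remove, and the filter does remove them; (f)
TE intervals overlapping a configurable fraction (0.44) of precursor loci;
(g) two pseudo-species best-hit tables planting homolog categories with
II most frequent (I 0.25 / II 0.50 / III 0.25).

Defaults are 6 tissues × 2 replicates per assay. Site placement is 75 % CDS,
15 % 3′UTR, 10 % 5′UTR. Planting uses replacement semantics: the site
overwrites bases at its position, so transcript length is independent of the
distortion (an indel changes the site footprint by one base, not the
transcript).

Not emulated: read-level sequencing (no FASTQ), splice-graph realism beyond
single-segment skipping, genomic sequence context (each transcript sits on
its own scaffold, intronless, + strand), miRNA biogenesis, and kinetic
repression — coupling acts on mean expression profiles, because the analysis
measures correlation, not kinetics. Passing tests therefore demonstrate
correctness of the statistical machinery on data satisfying its assumptions,
not performance on real tissue libraries with batch effects, isoform
quantification uncertainty or shared-sequence cross-mapping.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design: default
synthetic studies use 60–500 genes (≈140–1250 isoforms), 20 miRNAs and 12–24
samples, with network minimum module size scaled to the feature count; the
planted-block network checks run at ≈2000 isoforms. All randomness flows
from a single integer seed through one `numpy` generator; the same seed
yields byte-identical datasets, and the pipeline manifest records every
threshold actually used plus a configuration hash.

## Known limitations

* The GFF3 reader targets intronless transcript models (mRNA span = mature
  transcript; UTR/CDS children must tile it). Multi-exon models would need
  exon-aware coordinate projection.
* The NB exact-style test shares one common dispersion across features; no
  empirical-Bayes shrinkage or tagwise dispersion.
* The static-height tree cut can, in principle, chain distinct modules that
  a dynamic cut would separate; at the simulated separation levels this does
  not occur.
* Wallenius quadrature is accurate for the moderate margins used in
  enrichment tables; extreme margins (thousands of draws) would warrant a
  saddlepoint or recursive evaluation.
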
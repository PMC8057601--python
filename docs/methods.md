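# Methods

## Coordinate and annotation model

All internal coordinates are 0-based half-open; GFF3 I/O converts to and
from that format's 1-based closed convention. Genes are represented by the
union of their exon intervals (across all transcripts); TEs by their spans.
Before counting, exon bases are subtracted from TE spans, so a read in an
exon supports the gene while a read in a TE-containing intron supports the
TE. TEs wholly inside exons become empty after subtraction and are dropped
from counting (logged, since their fate is otherwise undefined). TE inputs
are expected to be disjoined; if overlapping TE records are supplied, later
records (by sort order: chromosome, start, id) are truncated against
earlier ones with a warning, so behavior on imperfect input is
deterministic. The two parental annotations are then concatenated under
renamed, collision-free chromosome names (`<genotype>_<chrom>`), each
feature keeping its genome of origin.

## Read assignment

Only unique-mapping fragments are counted (SAM input: NH tag = 1, or MAPQ ≥
30 when NH is absent; mates of a pair are merged into one fragment spanning
the union of their blocks). Assignment is union-mode: ≥ 1 base of overlap
with exactly one feature increments that feature; overlap with two or more
features is ambiguous and counts to none; everything else is tallied as
no-feature. Assignment is unstranded by default — the upstream protocol is
strand-aware but the counting convention is not documented, so a
`stranded` flag is provided and off by default. Per-library tallies
(assigned / ambiguous / no-feature / non-unique) always sum to the number
of input fragments; this conservation is asserted in tests.

Library sizes for RPM normalization default to the total unique-mapped
fragments per library and can be overridden per sample via the sample
sheet, since external size estimates (e.g. from a SNP-ASE alignment of the
same reads) may be preferable and their derivation is not standardized.

## RER

RER = m / (m + p) with m, p the arithmetic means of RPM across replicates
where the feature's genome was inherited maternally / paternally. RER is
undefined (NaN, never imputed) when m + p = 0. A feature is *assessable*
with ≥ 10 unique reads summed over all libraries of the contrast; the
threshold is inclusive and applied to the contrast total (a per-library or
per-direction variant would be stricter; the contrast total matches how
the ratio itself pools libraries). Bins: strong maternal/paternal beyond
0.9/0.1, moderate beyond 0.8/0.2, all strict.

## Dosage test

Because endosperm is 2m:1p, the null is a two-fold maternal excess. Each
feature is tested with a threshold Wald statistic W = (|lfc| − 1)/se,
p = min(1, 2·Φ̄(W)), i.e. H0: |lfc| ≤ 1 against |lfc| > 1, then BH
adjustment across features. Model choices:

* **Size factors**: median-of-ratios over features nonzero in every
  library; fallback to library-total scaling (geometric mean 1, empty
  libraries pinned at factor 1) with a warning when no such feature exists.
* **Dispersion**: per-feature method-of-moments on normalized counts
  within each inheritance group, solving var = mean·E[1/s] + α·mean²,
  pooled across groups by degrees of freedom and floored at 1e-8. With
  three replicates per group this is noisy but unbiased enough for the
  operating characteristics below; no trend shrinkage is applied by
  default.
* **Effect and SE**: lfc = log2(m̄_mat + ½) − log2(m̄_pat + ½) on
  normalized group means; the half-count offset keeps all-zero groups
  finite and biases the null lfc slightly *below* 1, which is
  conservative. The SE is the NB delta method on the two group means.
* **Independent filtering analog**: features with total count < 10 in the
  contrast are excluded before testing and before BH.

This is deliberately not a reimplementation of a full shrinkage-based
differential-expression fit (no empirical-Bayes lfc shrinkage, no Cox–Reid
dispersion, no outlier handling). The contract is operating
characteristics, verified by simulation: at exact 2:1 dosage with NB noise
(α = 0.1, 3+3 replicates, 2,000 features) ≤ 1% of features are called
imprinted (observed: 0), and fully monoallelic features with per-direction
mean normalized count ≥ 50 are recovered as MEG/PEG ≥ 90% of the time
(observed: 100%) with false-discovery proportion ≤ 5% (observed: 0).

## Classification

MEG/matTE: padj < 0.05, maternal direction, RER > 0.9. PEG/patTE: padj <
0.05, paternal direction, RER < 0.1. All inequalities strict, so boundary
values are never called imprinted. Maternal *gene* calls flagged by the
pericarp filter become `excluded_pericarp` (paternal calls and TEs are
never gated by it); paternal TE calls in contrasts marked unreliable (a
per-contrast flag, intended for parents with weaker assemblies in
intergenic space) become `excluded_paternalTE_contrast`. Each genome's
allele is tested and classified independently; cross-genome agreement is a
separate downstream step.

## SNP-ASE

Per gene and direction, ratio = maternal reads / informative reads, with
replicates summed within a direction and ≥ 10 informative reads required
(inclusive). Classification from the two reciprocal ratios with cutoffs
0.85/0.15 (strict): both high → maternal-biased, both low →
paternal-biased, discordant extremes → genotype-biased toward the genotype
whose allele is high in both directions. The discordant-extreme pattern is
treated as genotype bias (not parent-specific expression): the reciprocal
flip is exactly what a genotype effect produces and what a parental effect
cannot.

## Tissue filters

Pericarp contamination: flagged when mean pericarp expression > 2× mean
endosperm expression (strict). Endosperm-preferred: endosperm + whole-seed
libraries carry > 60% of the summed expression across all libraries
(strict; zero-total features are not preferred). Both rules are
scale-invariant; the composition of the atlas (which libraries carry which
class) is metadata supplied with the matrix, not a parameter. Flags
propagate to orthologs of flagged genes through the ortholog map.

## Downstream comparisons

Cross-genome consistency partitions imprinted features into shared
(counterpart exists in the other genome's calls with the same category),
assessable-but-not-shared (counterpart present in the calls but different),
and unique-to-one-genome (no map entry, or the map partner was never
assessed — the latter is grouped with unique because "shared" is defined on
features that *could be assessed* in both genomes). Nearest-gene distances
re-implement signed closest-feature search: magnitude is the interval gap
(0 on overlap), sign is positive when the TE lies downstream of the gene in
the gene's orientation; ties break to the smaller gene start, then lexical
id (the reference tool's tie behavior is unspecified). Enrichment wrappers:
exact binomial upper tail P(X ≥ k) with fold = (k/n)/p; Pearson chi-square
without continuity correction by default (configurable for 2×2); Welch's t
for distance and LTR-similarity comparisons, with the identical-constant
case defined as (t, p) = (0, 1).

## Synthetic data generator

The generator encodes the study design as its defaults: two genotypes
crossed reciprocally, three replicates per direction, NB noise with mean μ
and variance μ + αμ² (α = 0.1), base mean 100 on the count scale (the
maternal-direction mean of a biparental feature), and log-normal library
size variation (σ = 0.2) to exercise normalization. An allele with maternal
copy fraction f (0.5 = biparental, 1.0 = fully maternal; default 1.0 for
imprinted classes) has expected counts 2·(μ/2)·2f maternally and
μ·(1 − f) paternally, i.e. the 2:1 copy dosage times per-copy activity.
Class counts (300 biparental, 50 MEG-like, 50 PEG-like, 50 genotype-biased,
30 PAV maternal TEs, 20 PAV silent) are desk-scale defaults chosen to give
stable operating-characteristic estimates in seconds on one CPU; the
acceptance recomputation raises the biparental count to 2,000. Counts are
drawn at the allele level, so the SNP-ASE allele-count table is exactly
consistent with the RER count table, and genotype-biased genes emerge with
flipping SNP-ASE ratios but dosage-proportional RER by construction rather
than by post-hoc labeling. Separate helpers generate a toy two-genome
annotation with alignment records whose assignment fate (gene, TE,
ambiguous, no-feature, non-unique) is known by construction, and a tissue
atlas with planted pericarp-contaminant, endosperm-preferred and
constitutive profiles.

What the generator does **not** emulate: sequence-level reads (no mapping
bias, no alignability structure), paralog cross-mapping, partial
maternal-tissue contamination gradients, correlated features, or
overdispersion heterogeneity across features. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every artifact of real libraries.

## Numerical details and limitations

* Undefined quantities (RER with zero expression, SNP ratios under the
  read minimum, dispersion of all-zero features) propagate as NaN or are
  skipped; they are never imputed.
* The Wald SE is floored at 1e-8; the p-value caps at 1 by construction.
* With only three replicates per direction the MoM dispersion is noisy;
  the threshold test remains conservative in simulation because the
  half-count offset shrinks |lfc| toward the null. Very low counts are
  handled by the total-count filter rather than by modeling.
* Seeds fix all randomness; identical configuration and seed reproduce
  byte-identical outputs, asserted down to file digests in the CLI tests.
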
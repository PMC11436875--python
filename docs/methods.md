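# Methods

## Overview

`crevar` nominates non-coding candidate variants for Mendelian disorders
of a specific cell type by intersecting three sources of evidence:
pedigree segregation, population rarity/conservation, and chromatin
accessibility in the disease-relevant cell type. The package also carries
the downstream statistics that make such a nomination defensible:
enrichment of candidates in the peak set versus random regions, linking
of peaks to their likely target genes, agreement metrics for the
cell-type clustering that produced the peak atlas, and an exact test of
allelic imbalance for experimental follow-up. Because the cohort data
such a framework is built for are access-restricted, the package ships a
synthetic-cohort generator that produces every input with known planted
truth; all tests and the acceptance script run against it.

## Variant model and hard filters

Variants are held biallelic. Multi-allelic records are split one record
per alternate; spanning-deletion alleles (`*`) are dropped, and each
sample's genotype is recoded against the focal alternate (alleles other
than the focal one count as reference). Site-level gates: gnomAD and
TOPMed allele frequency strictly below 10⁻³ for monoallelic
(dominant/de novo) searches and 10⁻² for biallelic (recessive) searches;
GERP strictly above 2; the record must pass upstream VCF quality filters.
Genotype-level gates apply to every genotype an inheritance decision
consumes: GQ > 20, and for heterozygous calls an allele balance
(alt depth / total depth) > 0.15; a symmetric variant
(min(AB, 1−AB) > 0.15) is available as an option.

Choices worth noting:

- **Missing population AF is treated as 0**: absence from the reference
  panels is evidence of rarity, not missingness to be penalized. This is
  a documented knob.
- **Boundary behavior is strict** (`<` for AF, `>` for GERP/GQ/AB), so a
  variant exactly at a threshold fails.
- Indel left-normalization is assumed done upstream.
- Genomic context labels (exonic / promoter / intronic / intergenic) use
  the precedence exonic > promoter > intronic > intergenic; the promoter
  window is TSS −2000/+200 bp, strand-aware. Both are configuration, not
  biology claims: annotation sources rarely agree on "promoter."

## Inheritance searches

Five configurations per family:

- **De novo**: affected child heterozygous (passing GQ/AB), both parents
  confidently homozygous reference. This is a genotype-rule caller, not a
  likelihood model — a deliberate simplification; a genotype-likelihood
  caller would recover borderline calls near the GQ gate that this rule
  refuses.
- **Dominant**: every affected member carries the allele; no unaffected
  member carries it. **Incomplete penetrance** drops the within-family
  unaffected exclusion (a per-family flag, since plausible modes are a
  per-pedigree judgment).
- **Homozygous recessive**: every affected homozygous alternate, no
  unaffected homozygous alternate, and genotyped parents of affecteds
  must carry the allele (a hom-ref parent is transmission-inconsistent).
- **Compound heterozygous**: the accessibility peak, not the gene, is the
  unit of heredity. A pair (v1, v2) in the same disease-relevant peak
  qualifies when the affected child is het at both, v1 was transmitted by
  the unaffected father and v2 by the unaffected mother. Parental origin
  is inferred from trio genotypes; sites where both parents carry the
  allele are ambiguous and skipped with a warning, never guessed. Both
  members are gated at the biallelic (10⁻²) AF threshold.
- **Cohort exclusion**: dominant-class calls die if any unaffected
  individual cohort-wide carries the allele; recessive-class calls only
  if an unaffected individual is homozygous alternate. Unaffected
  carriers inside a family flagged for incomplete penetrance do not
  poison that family's own call.

Solved or QC-failed pedigrees are removed by a config blocklist.

## Peak atlas and interval arithmetic

Intervals are BED-convention 0-based half-open; variant positions are
VCF 1-based; the conversion lives in exactly one module. Merging is
`bedtools merge` semantics including book-ended intervals (distance 0),
verified against the tool itself in the test suite. Disease groups map
to one or more cell types (e.g. Duane syndrome → abducens cMN6; Moebius
→ cMN6 and cMN7); the group's search space is the union-merge of the
mapped cell types' peak sets. Overlap rules: SNV/indel by anchor-position
containment (half-open bounds — a variant at the interval end is
outside); SV by any-overlap of the span; mobile-element insertion by
point overlap after padding peaks ±15 bp for breakpoint uncertainty.
Indel overlap uses the anchor position only; span-based overlap is a
config option.

## Aggregation and effect scores

Multi-hit peaks collect candidates within a peak across families; a peak
qualifies with ≥ 2 families sharing one broad mode (dominant =
de novo/dominant/incomplete-penetrance; recessive = homozygous/compound
het). SVs longer than 100 kb, or whose span overlaps an exon
("clear coding etiology", operationalized via the gene model and
config-overridable), are excluded before counting. Multi-hit genes are
genes with ≥ 2 distinct linked peaks each containing a dominant
candidate. Phenotype stratification uses Fisher's exact test (sample
odds ratio ad/bc with infinity on zero cells; conditional hypergeometric
two-sided p).

Predicted accessibility-difference (SAD) scores arrive as raw values
from an external sequence-to-accessibility model (the model itself is
out of scope). SNV scores are z-normalized against the SNV mean/sd;
indels are scored against the same SNV null because an indel-only null
is not well defined. |z| > 2 flags predicted significant effects.
z-scores are invariant to affine rescaling of the raw scores.

## Permutation enrichment

The null randomizes **regions**, not variants: each of N iterations
draws a size-matched, mutually non-overlapping placement of the peak set
uniformly over the unmasked genome and recounts variant hits. Placements
may move across chromosomes (matching the default resampling of
regioneR-style tools); a per-chromosome restriction would be a
straightforward variant. Placement is longest-first with incremental
masking: each placement is uniform over all currently feasible start
positions, which is exact for a single interval and a good approximation
for sparse peak sets (for near-saturated genomes the ordered scheme
biases against fragmenting large gaps — documented, not corrected).
Individuals with > 75 filtered genome-wide de novo calls are dropped
before testing as call-quality outliers. The empirical p uses the
add-one estimator (1 + #{null ≥ obs})/(1 + N), so p is never 0 and its
floor at N = 5000 is ≈ 2.0 × 10⁻⁴; z = (obs − mean)/sd of the null, and
is reported missing when the null is degenerate (sd = 0).

## Peak-to-gene links and DORC

Per-cell counts are too sparse to correlate directly, so cells are
summed into k metacell groups (default k = 100; grouping pluggable — an
embedding-based k-means or, for synthetic data, random assignment, which
is unbiased because correlation is planted per cell). For every
(peak, gene) pair with |TSS − peak midpoint| ≤ 500 kb, the Pearson r
across aggregates is tested via the t-transform (df = k − 2); BH
adjustment is over all tested pairs in the run (one global family);
links are retained at r ≥ 0.1 (one-sided positive retention; the ≥ vs >
boundary is a config flag) and FDR < 10⁻⁴. Gene ranking restricts to
±50 kb, assigns each peak to its lowest-FDR gene (ties: larger |r|, then
lexicographic gene id), and reports per-gene link counts with
percentile ranks. DORC scores are Σ count(cell, peak)/fragments(cell)
over a gene's linked peaks — exactly invariant under per-cell depth
rescaling. Concordance against activity-by-contact predictions reports
the fraction of ABC enhancers overlapping any linked peak
(matched peak) and the fraction whose overlapping peak shares the
cognate gene (matched gene).

## Cluster agreement metrics

Homogeneity, completeness, V_β and per-cluster purity are computed from
the class × cluster contingency table with natural-log entropies
(h, c, V are entropy-ratio quantities and therefore log-base invariant;
stored raw entropies are in nats). Conventions: 0·log 0 = 0; h = 1 when
H(C|K) = 0 (including the degenerate single-class case), symmetrically
for c. Purity's denominator is read as the cluster's size — the only
reading bounded in [1/|C|, 1]. Note that under cluster refinement h is
monotone non-decreasing and H(K|C) non-increasing is **false** —
H(K|C) grows, but so does H(K), so normalized completeness itself can
move either way; the tests assert the true monotonicities.

## Allelic imbalance (binomial ATAC)

With n informative reads and k reference reads at a heterozygous site,
the two-sided exact p sums the binomial(π₀) probability of every outcome
whose probability does not exceed that of the observed one. Outcomes
within a relative 10⁻⁷ of the observed pmf count as ties, stabilizing
the ≤ comparison under floating point. Replicates pool by summation and
are also reported individually. The interval estimate is Clopper–Pearson
(exact) by default, Wilson as an option; at k/n ≈ 0.81 with n ≈ 149 the
95% interval is [0.73, 0.87].

## Synthetic data: what it emulates, what it does not

The generator targets a three-chromosome, 10 Mb-per-chromosome assembly
with the first 10% of each chromosome masked. Defaults: one family per
disease group × subgroup (28 trios: familial subgroups have an affected
parent), one planted candidate per family with the mode chosen to fit
the structure, planted dominant multi-hit peaks on request, and
background variants that each carry exactly one disqualifying annotation
(common AF, low GERP, or a failed upstream filter, chosen uniformly) —
so in the noise-free limit planted recovery has precision = recall = 1
by construction, and the recovery tests verify the pipeline rather than
the generator. Population AFs follow a mixture (30% private at 0, 40%
Beta(0.5, 5)-scaled rare below 5 × 10⁻³, 30% common uniform on
[10⁻², 0.5]) so the filtering thresholds fall inside the spectrum.
Non-planted genotypes are transmitted Mendelianly from binomially drawn
founder genotypes, with an optional uniform mis-genotyping rate.

Count matrices are negative binomial (dispersion 0.1, base mean 5) with
a lognormal per-cell depth factor (log-sd 0.1) via a Gaussian copula;
planted (peak, gene) pairs share a latent Gaussian at the target
correlation. The copula transform attenuates Pearson correlation mildly
(≈ 0.8 → ≈ 0.76 at these settings), which the ±0.15 recovery tolerance
absorbs. The small depth log-sd keeps depth-induced correlation between
unrelated features near zero while still exercising DORC depth
normalization.

Deliberately not emulated: sequence content and reads, linkage
disequilibrium, realistic per-chromosome peak density, batch structure
in the count matrices, mapping bias in allele counts, and the
sequence-to-accessibility predictor. Passing tests therefore demonstrate
correctness of the decision logic and statistics under clean conditions,
not robustness to real-data artifacts (genotyping error is the one noise
source with a knob).

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen to make
each statistical check well-powered: 1000-cell matrices with 100
metacells for link recovery, 50 replicate cohorts for multi-hit
recovery, 50 null runs for permutation calibration, 10 000 draws for the
exact-test type-I rate, and a single 5000-iteration permutation for the
p-floor. Pmf tie tolerance 10⁻⁷ (relative); entropy branch tolerance
10⁻¹²; correlation clipped to [−1, 1] before the t-transform.
Reproducibility: every stochastic routine takes a seed or Generator;
identical seeds give byte-identical emitted files.

## Known limitations

- De novo calling is rule-based; no genotype-likelihood model.
- X-linked and mitochondrial inheritance are not modeled.
- Region randomization is approximate-uniform for multi-interval
  placements (ordered rejection-free placement).
- The cohort-scale headline counts of a real study (tens of millions of
  variants filtered to thousands of candidates) are not reproducible at
  synthetic desk scale; the package instead verifies each rule and
  statistic against oracles and planted truth.
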
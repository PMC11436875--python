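# crevar

Cell type-aware nomination of non-coding Mendelian disease variants.

## The problem

Most unsolved Mendelian pedigrees lack an obvious pathogenic coding
variant, but a whole genome contains tens of millions of variant calls —
far too many to interpret. When the disease arises from a failure of a
specific cell type (here the motivating case is the congenital cranial
dysinnervation disorders, where cranial motor neurons develop or wire
incorrectly), the *cis*-regulatory elements accessible in that cell type
define a biologically principled search space: a non-coding variant can
only plausibly break a regulatory element that is active in the affected
cells.

`crevar` implements that framework as a library for statistical
geneticists and regulatory genomicists:

- **Hard filtering** of jointly genotyped variants: gnomAD/TOPMed allele
  frequency < 10⁻³ (dominant/de novo searches) or < 10⁻² (recessive),
  GERP > 2, upstream VCF filters passed, genotype quality > 20, and
  heterozygous allele balance > 0.15.
- **Inheritance searches** per pedigree: de novo, dominant, dominant with
  incomplete penetrance, homozygous recessive, and compound heterozygous —
  with the accessibility **peak as the unit of heredity** for compound
  hets (one variant from the unaffected father and a different variant in
  the *same peak* from the unaffected mother), plus cohort-level exclusion
  against unaffected carriers.
- **Peak restriction**: SNVs/indels by positional containment in the
  disease group's merged peak set, SVs by any-overlap with cohort AF
  < 0.005, mobile-element insertions by ±15 bp padded-point overlap with
  class-specific AF gates (0.01 inherited, 0 de novo) and call-confidence
  labels.
- **Allelic aggregation**: multi-hit peaks (≥ 2 families, one broad
  inheritance mode, SVs > 100 kb excluded) and multi-hit genes (≥ 2
  linked peaks carrying dominant candidates), plus Fisher's exact
  phenotype stratification.
- **Permutation enrichment**: observed variant counts in peaks versus
  5000 size-matched, non-overlapping random placements over the unmasked
  genome; z = (obs − mean)/sd of the null, empirical p with the add-one
  floor 1/(N+1).
- **Peak-to-gene links**: Pearson correlation of accessibility and
  expression across metacell aggregates within ±500 kb of each TSS,
  retained at r ≥ 0.1 and BH FDR < 10⁻⁴; per-gene link ranking (±50 kb,
  lowest-FDR peak assignment) and per-cell DORC scores (depth-normalized
  accessibility summed over a gene's linked peaks).
- **Cluster agreement metrics**: homogeneity, completeness, V-measure
  (V_β = (1+β)hc/(βh+c)) and per-cluster purity from the class × cluster
  contingency table.
- **Binomial ATAC**: the exact two-sided binomial test
  P = Σ_{i : Pr(X=i) ≤ Pr(X=k)} C(n,i) π₀^i (1−π₀)^(n−i)
  of reference versus mutant read counts at a heterozygous regulatory
  site, with Clopper–Pearson intervals.
- **A synthetic-cohort generator** that emits every input above with
  planted, recoverable truth, so the whole pipeline is testable at desk
  scale without any restricted-access data.

## Worked example

```bash
python examples/01_simulate_and_nominate.py
```

```
cohort: 28 families, 187 variants (32 planted candidates)
nominated 32 candidates; recall 1.00, precision 1.00
multi-hit peak chr1:1534980-1535480 (dominant) hit by families ['F0000', 'F0001']
multi-hit peak chr1:1743531-1744031 (dominant) hit by families ['F0004', 'F0005']
```

The generator plants one candidate per family (mode chosen to fit the
pedigree structure) and two dominant multi-hit peaks; every background
variant carries at least one disqualifying annotation. Recall and
precision of 1.00 mean the filter → inheritance → peak-overlap → cohort
exclusion cascade recovered exactly the planted candidates, and the two
recurrently hit peaks are the ones planted in two families each.

The allelic-imbalance example:

```bash
python examples/05_binomial_atac.py
```

```
rep1: 62/75 reference reads, p = 8.40e-09
rep2: 53/75 reference reads, p = 4.50e-04
pooled: 115/150, estimate = 0.77, ref/mut ratio = 3.29
95% CI [0.69, 0.83], two-sided exact p = 3.77e-11
```

A pooled reference-allele fraction far above 0.5 with a vanishing exact
p-value indicates consistent depletion of the mutant allele in *cis* — a
loss-of-function regulatory effect measured with internal calibration.

Other examples cover peak-to-gene linking and DORC scores (`02`),
permutation enrichment (`03`), and cluster metrics (`04`).

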
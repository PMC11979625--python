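# pleiopwas

Tools for asking whether two complex traits share genetic risk factors, and
for pinpointing the genes that carry that shared risk — using nothing but
GWAS summary statistics, a cis-protein-weight reference, and expression
matrices. The package is aimed at statistical geneticists studying comorbid
trait pairs (the motivating case is a pair of neurodegenerative diseases
with overlapping pathology), and it ships a seeded synthetic-data generator
so every stage can be exercised, calibrated, and tested without access to
restricted cohort data.

## The three stages

**1. Proteome-wide association (PWAS).** For each gene, cis-SNP weights
`w` predicting its protein abundance are trained on a reference panel by
four model families — `top1` (single best marginal SNP), `blup`
(cross-validated ridge), `lasso`, and `enet` (elastic net, mixing 0.5) —
with the family chosen by k-fold cross-validated R². The gene's association
with a trait combines those weights with the trait's GWAS z-scores:

```
z_pwas = (wᵀ z) / sqrt(wᵀ R w)
```

where `R` is the cis-window LD matrix. The denominator is the null variance
of the linear combination, so `z_pwas ~ N(0,1)` for a trait-irrelevant
protein regardless of the weights. Two-sided p-values follow from the normal
tail; Bonferroni and Benjamini–Hochberg corrections are available.

**2. Conditional / conjunctional FDR (condFDR / conjFDR).** Association
with a second trait reranks variants for the first. The empirical-Bayes
estimate

```
condFDR(p1 | p2) = p1 · W(p2) / W(p1, p2)
```

uses LD-pruning-weighted counts `W` of variants passing the p-value
thresholds (jointly and for the conditioning trait alone), binned on a
−log10 grid, capped at 1, and made monotone. The conjunctional FDR is the
maximum of the two reciprocal condFDRs — a conservative posterior bound on
a variant being null for *either* trait. Variants with conjFDR below 0.01
are clumped into loci by LD (r² ≥ 0.1 to the seed), each locus is
represented by its minimum-conjFDR lead SNP, leads are mapped to genes by
interval containment, and direction-of-effect concordance across the traits
is reported. Conditional Q–Q curves visualize the cross-trait enrichment
the method exploits.

**3. Differential-expression validation.** Candidate genes are checked for
expression shifts between patient and control groups: a Kolmogorov–Smirnov
normality pre-check with a parametric-bootstrap reference, then a Welch
t-test (two groups) or one-way ANOVA (three or more), called at p < 0.05,
with group means reported so the direction (e.g. downregulation in cases)
is explicit.

A gene flagged by all three stages — PWAS-significant for both traits,
hosting a conjFDR locus, and differentially expressed in the expected
direction — is the pipeline's high-confidence shared risk gene.

## Worked example

`examples/05_full_pipeline.py` plants one gene as simultaneously (a) the
cis-regulator of its protein, (b) a shared causal factor for both traits,
and (c) downregulated in cases, then runs all five stages:

```
$ python examples/05_full_pipeline.py
stages run:            simulate, fit_weights, pwas, pleiofdr, de
planted gene:          ['GENE0001']
PWAS overlap (both traits): ['GENE0001']
conjFDR loci:          13 | genes at loci: ['GENE0001', 'GENE0015']
DE down-called genes:  ['GENE0001', 'GENE0020']
convergent genes:      ['GENE0001']
```

The planted gene is recovered by every stage; the extra loci and DE calls
come from the scenario's own polygenic background and the 5% test level.
The other examples exercise one capability each: scenario structure
(`01`), weight training + PWAS (`02`), condFDR/conjFDR and locus clumping
(`03`), and the expression tests (`04`).

The same pipeline is available from the shell:

```
pleiopwas run --seed 2 --out-dir pipeline_out
pleiopwas simulate | fit-weights | pwas | pleiofdr | de   # stage by stage
```

Each run writes its per-variant and per-locus TSVs, Q–Q and Manhattan
figures, truth records, and the fully-resolved YAML config next to its
outputs.

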
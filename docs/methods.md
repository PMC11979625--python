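# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Synthetic data model

The generator produces every input the pipeline consumes, as a pure
function of a `ScenarioConfig` and a seed.

**LD reference.** Variants are grouped into blocks laid out along
chromosomes 1–22 with a 1 Mb inter-block gap and 1 kb spacing. Within a
block the correlation is AR(1), `R[i,j] = rho^|i-j|` (default
`block_rho = 0.8`); across blocks it is exactly zero. The AR(1) choice is
deliberate: closed-form entries make every LD-dependent computation —
quadratic forms, pruning, clumping — checkable against hand arithmetic.
MAF is drawn once per block, uniform on `maf_range = (0.05, 0.5)`. Variants
in tight LD share coalescent history and hence allele frequency in real
panels; beyond realism, very unequal MAFs cap the achievable genotype
correlation (a Fréchet-bound effect) below high LD targets, so constant
within-block MAF is what makes an exact AR(1) genotype correlation target
attainable.

**Genotypes.** Hard genotypes in {0,1,2} with binomial(2, maf) marginals
are produced by thresholding a latent Gaussian vector. A naive Gaussian
copula attenuates correlations badly (a latent 0.8 yields genotype
correlations near 0.66), so the latent correlations are adjusted: for the
genotype step function `G = 1{Z>t1} + 1{Z>t2}` the Hermite coefficients
have the closed form `a_k = φ(t1)He_{k-1}(t1) + φ(t2)He_{k-1}(t2)`, making
the genotype covariance at latent correlation r the explicit power series
`Σ_k a_k² r^k / k!`. The latent correlation for each lag is found by
bisection on that series, and the resulting matrix is projected back to the
PSD correlation cone by eigenvalue clipping (the adjustment can leave
eigenvalues marginally negative, order 1e-3). Empirical genotype LD then
matches `rho^|i-j|` with residual systematic error well below 0.01;
remaining deviation at finite sample size is sampling noise
(SE ≈ (1−ρ²)/√n per pair).

**Protein abundance.** Each of `n_genes` genes (default 50) is assigned a
cis window of `cis_window_bp` (default 40 kb, i.e. ~41 variants) centred in
its own block. `n_causal_cis` SNPs (default 1) receive standard-normal
effects; abundance is `Gβ + ε` with the noise variance set from the
*theoretical* genotype covariance so the genetic variance fraction equals
`h2_cis` in expectation (default 0.3, a typical strong brain cis-pQTL
signal). `h2_cis = 0` with causal SNPs (or vice versa) is rejected as
contradictory. The default training size `n_ref = 400` mirrors a
~400-donor proteomic reference panel.

**GWAS summary statistics.** Binary traits are represented directly by
their summary z-scores (liability-scale effects) rather than by
individual-level case-control sampling: the pipeline consumes only summary
statistics, and the direct representation keeps the null distribution
exact. Causal status is a four-component mixture per variant —
shared / trait-1-only / trait-2-only / null with probabilities
`(pi_shared, pi1, pi2, remainder)`, defaults 0.002 each. Per block,

```
z = sqrt(N) · R β + ε,   ε ~ MVN(0, R)
```

so effects are LD-smeared and noise is LD-correlated within blocks,
independent across traits. Shared causal variants receive the *identical*
effect in both traits: genuinely pleiotropic variants should produce
concordant directions, which is the property the concordance check
measures; independent per-trait draws would randomize the signs of true
shared signals. Effect sizes are normal with `sigma_beta = 0.05`
(a modelling convention — typical per-variant liability effects at these
GWAS scales, giving causal |z| around 3–5); `n_gwas1 = 8477` and
`n_gwas2 = 6618` mirror case-control GWAS of roughly 4.2k+4.2k and
2.6k+4k samples. `planted_shared` injects fixed-effect shared variants on
top of the mixture for recovery experiments. p-values are the two-sided
normal tail of z, floored at 1e-300 so log-scale binning never sees zero.

**Expression.** Log-scale values with per-gene baselines ~N(8, 2²) and unit
within-group noise; planted shifts are stated in baseline-SD units (the
default planted effect is −2 SD in cases, a strong but realistic
knockdown-scale change at n = 10 vs 10).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: imputation uncertainty and variable SNP coverage,
population stratification and relatedness, realistic LD (long-range,
non-stationary, MHC-scale haplotypes), case-control ascertainment effects,
proteomic batch structure, and count-distributed RNA-seq noise (expression
is Gaussian on the log scale by construction). Results on synthetic data
certify the statistical machinery, not robustness to those artefacts.

## PWAS stage

Weights are fit per gene on the cis-window genotype matrix. `top1` selects
the SNP with maximal |marginal z| and uses its OLS coefficient; `blup` is
ridge regression with the penalty chosen by cross-validation (the standard
equivalence, avoiding a mixed-model solver); `lasso` and `enet`
(l1_ratio 0.5) tune their penalties by internal 3-fold CV on each training
fold. Model selection uses out-of-fold R² from a seeded outer k-fold
(default 5); a family whose final weight vector is identically zero is
excluded from selection with a logged warning. Constant abundance or
all-constant genotypes yield a flagged degenerate model, never an error. A
fifth, MCMC-based sparse Bayesian family seen in some weight references is
not implemented; the model dictionary is open so one can be added.

The association statistic divides `wᵀz` by `sqrt(wᵀRw)` — the "linear sum
of z × weight" normalized by its null variance, without which the sum is
not a z-score. R comes from the LD reference (block-diagonal submatrix).
Alleles are aligned by flipping z where effect/other alleles are swapped;
strand-ambiguous (A/T, C/G) SNPs are dropped by default because they are
unresolvable without strand metadata. Weights of SNPs missing from the
GWAS are set to zero and the denominator is recomputed on the present
subset (common TWAS practice); genes with under 50% of their SNPs matched,
or with `wᵀRw ≤ 1e-12`, are skipped with an explicit reason. The default
multiple-testing rule is BH-FDR at 0.05 with Bonferroni available and an
optional external test count `m` (for corrections spanning a full protein
reference rather than the genes actually tested).

## condFDR / conjFDR stage

The lookup is a 101 × 101 grid uniform in −log10 p over [0, 10], overflow
binned at the edge — resolution enough that bilinear interpolation error is
negligible next to counting noise, coarse enough that cells stay populated.
Counts are weighted by LD-pruning inclusion fractions: each of
`n_iter = 100` iterations keeps a random maximal subset with pairwise
r² ≤ 0.1 (greedy over a random priority order, per block), and a variant's
weight is its inclusion fraction. This keeps the empirical cdfs from being
dominated by large LD blocks; with `r2_max = 1` the weights are exactly 1
and the lookup equals the unweighted one.

The raw counting estimator `p1·W(p2)/W(p1,p2)` is nonmonotone in −log10 p1
wherever the joint count drops across a data point, so each p2 row is made
nonincreasing by a cumulative minimum; empty cells take the cap value 1.
Coordinates within 1e-9 of a grid node are snapped onto it — both when
counting and when interpolating — so that a variant whose p-value sits
exactly at a node threshold is counted as passing it regardless of which
side of the node `-log10(p)` lands on in floating point.

conjFDR is the per-variant maximum of the two reciprocal condFDRs, so
conjFDR < t implies both condFDRs < t by construction. Loci are formed by
greedy LD clumping of passing variants in ascending conjFDR order (ties
broken by smaller trait-1 p, then variant id, for determinism); clumping is
LD-based only, with `r2_clump = 0.1` and no distance merging, so nearby but
LD-independent signals remain distinct loci. No genomic-region exclusions
are applied by default; an exclusion list is configurable. Gene mapping is
interval containment of the lead SNP with a configurable flank (default 0).
Q–Q strata default to (1, 0.1, 0.01, 0.001), the convention for
conditional Q–Q plots; strata with fewer than 100 variants are emitted but
flagged low-count.

## Differential-expression stage

The validation claim is a per-gene p < 0.05 on already-normalized
expression, so the tests are a Welch unequal-variance t (two groups) and
one-way ANOVA (three or more), not a count-model or empirical-Bayes
pipeline. The KS normality pre-check estimates mean and SD from the sample,
which invalidates the textbook KS null distribution (anti-conservative), so
the reference distribution is a seeded parametric bootstrap (1000 draws,
each re-standardized the same way) and the p-value uses the
add-one estimator `(1 + #{D* ≥ D}) / (B + 1)`. Constant input returns
p = 0 with a degenerate flag. Zero mean difference returns statistic 0,
p = 1; zero within-group variance with a mean shift is flagged degenerate.
α is 0.05 to match the validation convention and is configurable. Raw and
BH-adjusted p-values are both reported; single-gene validation
conventionally reads the raw value, and the adjusted column is there for
multi-gene screens.

## Pipeline, formats, determinism

Stage seeds are spawned from the master seed via `SeedSequence`, so one
integer pins the entire run and identical configs produce byte-identical
TSVs. All formats are tab-delimited text with NA as the missing token and
10-significant-digit floats (round-trip exact at that precision);
coordinates are 1-based inclusive internally, with BED (0-based half-open)
converted at the boundary. Config parsing is strict — unknown keys fail
before any computation — and each run writes its fully-resolved config next
to its outputs. GWAS loading derives z from BETA/SE when Z is absent and
recomputes p from z when missing or inconsistent beyond 1e-6 relative,
logging the correction count; duplicate variant ids and out-of-range
p-values are load errors naming line numbers.

## Problem sizes used in tests and the acceptance script

The default scenario (20 000 variants, 200 blocks, 50 genes, n_ref 400) is
desk-scale: the full pipeline runs in ~13 s and the complete acceptance
script in under a minute on one CPU. Calibration and recovery checks use
20 seeds at 20 000 variants; the PWAS null check aggregates 50 fitted genes
across 10 independent null GWAS draws (weights are fixed quantities and the
z draws are the random element, so the 500 values follow the statistic's
null law exactly); weight-recovery checks use n = 2000 training samples per
seed. These sizes were chosen so that every documented guarantee is tested
at meaningful power while the suite stays fast enough to run on every
change.

## Known limitations

* The LD model is block-diagonal AR(1); conclusions about clumping and
  pruning behaviour under realistic long-range LD require real reference
  panels.
* condFDR lookups are bivariate only; more than two traits are out of
  scope.
* The weight-model family set omits MCMC-based sparse Bayesian regression.
* Strand-ambiguous SNPs are dropped rather than strand-resolved.
* The DE stage assumes normalized, roughly Gaussian expression values; it
  is not a substitute for count-based RNA-seq models when raw counts are
  available.
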
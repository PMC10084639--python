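# Methods

This note documents the models implemented in pleioscan, the estimation
choices behind them, what the synthetic cohorts do and do not emulate,
and the package's known limitations.

## Single-trait mixed model and score test

Per variant the model is

    y = W α + x β + u + ε,   u ~ N(0, G σ²ₐ),   ε ~ N(0, I σ²ₑ)

with y the drEBV vector, W an intercept (plus optional conditioning
covariates), x the 0/1/2 allele dosage and G the centred GRM
G = XcXc′/m (missing dosages mean-imputed, i.e. centred to zero). The
GRM of the fitted samples is eigendecomposed once; the variance ratio
λ = σ²ₐ/σ²ₑ is profiled by bounded 1-D REML optimisation on
log₁₀λ ∈ [−5, 5] (grid pre-scan, then Brent refinement) and **held fixed
across variants** — the score-test convention. Each variant then costs
O(n): with H = λS + I in the eigenbasis and P the projection removing W
under H, the statistic is (x′Py)²/(x′Px · σ̂²ₑ) against χ²₁, and the
reported β and se are the GLS fit at the null variance parameters, so
t = β/se satisfies t² = score statistic exactly and feeds the
meta-analysis without further assumptions.

Principal components are deliberately *not* added as covariates; the GRM
itself absorbs structure, and the null-cohort inflation factors near 1
(see `tests/test_acceptance.py`) support this for the simulated cohorts.

Conditional scans append the conditioning variants' dosages to W
(collinear ones dropped with a warning), refit λ, and exclude the
conditioned variants from the output.

## Heritability (weighted REML)

For drEBV with reliabilities r² and weights w = r²/(1−r²) the residual
is heteroscedastic: ε ~ N(0, D σ²ₑ) with D = diag(1/wᵢ). The problem is
whitened by D^(−1/2) and solved by the same profiled REML; standard
errors come from the inverse expected information at the optimum.

Two normalisations matter for interpretation and are applied to the
reported components:

- The centred GRM is not unit-diagonal — its mean diagonal is the
  average 2p(1−p) over variants — so the *average genetic variance per
  individual* is σ²ₐ·tr(G)/n, and that product is what `sigma_a2` and
  the h² ratio report. Without this correction h² would be
  overestimated by a factor ≈ 1/mean(2p(1−p)) on dosage GRMs.
- With weights, the fitted residual coefficient multiplies 1/wᵢ; the
  reported `sigma_e2` is the mean per-record residual variance
  σ²ₑ·mean(1/w).

Components are clamped at a floor of 1e-8·var(y); a flat GRM spectrum
(e.g. an identity GRM — unrelated individuals with no markers) makes the
ratio unidentifiable, and the result is returned with h² = 0 and
`converged=False` rather than an arbitrary interior value.

## Multivariate scan (mtGWAS)

The d-trait model replaces scalars with d-vectors; the covariance of the
stacked data is G ⊗ Vg + I ⊗ Ve. Vg and Ve are estimated once under the
global null by EM on the GRM-eigenrotated data: after also rotating
traits into the basis that jointly diagonalises (Vg, Ve) (generalised
eigendecomposition, Φ′VeΦ = I), every rotated sample is an independent
d-dimensional system with diagonal covariance sᵢΛ + I, so the E-step is
elementwise. Updates are projected onto the PSD cone; the likelihood is
monitored each iteration; convergence is a relative change < 1e-8 or 200
iterations (non-convergence is flagged, not fatal — EM's tail
iterations move the scan statistics negligibly). Per variant the
d-vector β is the GLS estimate under the null covariance and the test is
Wald χ² with d df. The same trait rotation makes the scan d independent
weighted regressions per variant, vectorised across variants.

Like the single-trait scan, variance components are *not* refitted per
variant under the alternative; this fixed-null approximation is the
standard score-test trade-off and is what keeps the scan O(nd) per
variant. With one trait the scan reduces exactly to the single-trait
t² (verified to 1e-6 in the tests; the dense Kronecker GLS oracle
agrees to 1e-6 on small instances).

The trait count is capped at 24 with a warning above 10: a d-trait scan
estimates d(d+1) covariance parameters under the null, and multivariate
mixed models are prone to over-parameterisation beyond ~10 traits.

## Meta-analysis (metaGWAS)

Signed t-values are assembled per variant over the intersection of the
traits' scans (variants missing from any trait are excluded — zero
filling would fabricate evidence of no effect). Effect alleles are
harmonised to the first trait's convention; a ref/alt swap flips the
sign, any other allele conflict drops the variant. V is the Pearson
correlation of the t-columns over markers (mode `all_markers`; a
`null_markers` mode restricting to |t| < 2 is available because strong
QTL inflate V). The statistic is χ² = t′V⁻¹t.

Degrees of freedom: the construction gives a χ² with d df under the
null, yet the methodology this follows is commonly evaluated with d−1
df. Both are implemented (`df_mode="d"` / `"d_minus_1"`, default
`d_minus_1` to match common practice); no report silently prefers one,
and calibration diagnostics always use the df matching the construction
so that λ_GC reads 1 under the null. With two overlapping traits the
choice shifts −log₁₀p by roughly a factor-two tail difference, so the
convention must be stated with any threshold.

Because each trait's t-values may come from scans on different
(overlapping) animal subsets, per-cell sample counts are carried in the
t-matrix; the complete-case design ("metaGWAS¹", same animals as the
multivariate scan) and the all-available design ("metaGWAS²") differ
only in which summary statistics are fed in.

## QTL calling and variance explained

QTL are runs of 1-Mb windows on a fixed grid (windows start at bp 1,
10⁶+1, …; the anchoring is a package choice made for reproducibility)
containing at least one variant below the threshold; adjacent
significant windows merge into one region — necessary for QTL spanning
several megabases under a 1-Mb definition. Leads are min-p with ties
broken by position then id. LD r² is the squared Pearson correlation of
dosages over pairwise-complete samples (unphased-genotype r²).

Variance explained per lead is 2p(1−p)β̂²/σ²·100% with p the lead's MAF
and σ² the phenotypic variance; β̂ comes from *one multiple regression
on all leads jointly* so that overlapping signals are not
double-counted; of a near-duplicate pair (r² > 0.99) the later lead is
dropped. On a single simulated cohort the marginal estimate also absorbs
polygenic effects of LD neighbours — an irreducible property of
marginal regression, which cancels in expectation; the recovery tests
therefore average over seeds.

## Evaluation layer

- Bonferroni threshold α/n_tests.
- Analytic FDR = P(1−A/T)/[(A/T)(1−P)], reported in percent (the scale
  on which such tables are printed); undefined (NaN) when A = 0.
- λ_GC = median observed χ²₁-quantile / 0.45494. Median-based because
  it is robust to true signal in the tail.
- Imputation accuracy: concordance ratio (best-guess call — dosage
  rounded, ties at 0.5/1.5 toward the heterozygote — equals truth) and
  squared Pearson correlation of dosages, overall and in truth-MAF bins.
- Method comparison: exact overlap decomposition over every method
  subset, QTL-level overlap, and paired −log₁₀p with its correlation.

## The synthetic cohorts

`simcohort` emulates a pig-breeding GWAS cohort built on deregressed
breeding values: hundreds–thousands of animals, 10³–10⁵ array SNPs with
MAF > 5% on multiple autosomes, up to 24 traits in named groups with
drEBV heritabilities anywhere in 0.04–0.67, modest within-group genetic
correlations (≈0.1–0.3), pleiotropic QTL worth ~0.2–11% of a trait's
variance, up to ~37% per-trait missingness, and reliability-derived
weights.

Mechanics and the reasoning behind them:

- **LD**: founder-haplotype blocks — each block of `ld_block_size`
  consecutive variants segregates on k = 8 founder haplotypes, each
  individual drawing two founders per block. This yields within-block
  r² averaging ≈ 1/(k−1) and zero between-block LD: enough structure
  for lead/neighbour fine-mapping at full experimental control and
  negligible cost. Allele frequencies are realised at founder-count
  granularity (multiples of 1/k), so very narrow `maf_range` settings
  are honoured only to ±1/(2k).
- **Phenotypes**: unit target variance per trait, split into QTL
  fractions (β = √(f·σ²/2p(1−p)), random sign), a polygenic part of
  size h² − Σf spread over all non-QTL variants with across-trait
  covariance from the genetic correlation matrix, and residuals whose
  per-record variance is (1−h²)/wᵢ normalised so the mean is 1−h² —
  exactly the weighted-REML model. Residuals are independent across
  traits; phenotypic correlation beyond the genetic part is not
  modelled.
- **Weights**: w = r²/(1−r²), the standard deregression weight form,
  with reliabilities uniform on `reliability_range` (default 0.4–0.95).
- **Missingness**: completely at random per trait; real missingness is
  plausibly informative (e.g. by herd or cohort), which is out of scope.
- **Determinism**: one integer seed expands into independent substreams
  (positions, genotypes, effects, noise, metadata) via seed-sequence
  spawning, so outputs are identical across runs and platforms at the
  dosage-integer level.

What passing tests on these cohorts do **not** show about real data:
there is no pedigree or family structure (all animals unrelated — which
is also why marker-GRM heritability is only weakly identified here and
the well-identified REML null test uses a constructed duplicate-pair
GRM), no selection, no mutation/recombination gradients, no genotyping
batch effects, and missingness carries no signal. Real-cohort QTL
counts, coordinates and candidate genes are not reproducible from
simulation and are not targets of this package.

## Numerical choices

- REML: bounded search on log₁₀λ with a 60-point pre-grid; boundary
  λ = 0 is explicitly compared against the interior optimum.
  Components floored at 1e-8·var(y).
- EM: initialisation Vg = Ve = Cov(Y)/2 + ridge; Ve floored at
  1e-8·(trace scale) so the generalised eigendecomposition stays
  defined; rank-deficient phenotype matrices flag `degenerate=True`.
- HWE: exact conditional test with probability ordering (no mid-p),
  computed by the standard two-sided recurrence from the modal
  heterozygote count; verified against full enumeration.
- Zero-variance variants are skipped and counted, never scored;
  p-values are clamped above 0 at the smallest positive double.
- V inversion: condition-number cap 1e8; a diagonal ridge is available
  but only applied when explicitly requested.
- Filter order (sample call rate → variant call rate → HWE → MAF → DR2)
  is fixed and each removal is attributed to the first failing filter,
  so QC report counts always reconcile.
- Merging drops every variant at a position carrying more than one
  allele pair ("both removed"): with array data there is no principled
  way to decide which record is right.

## Problem sizes used in the shipped checks

Test-suite simulations use n = 300–2000 animals and m = 300–5000
variants; null-calibration suites run 20 cohorts of n = 1000, m = 5000;
parameter-recovery suites average 12–20 cohorts at n = 2000. These sizes
make every property measurable with comfortable statistical margins
while keeping the whole suite in a few CPU-minutes.

## Known limitations

- No per-variant REML ("exact" mixed-model modes); score/Wald at the
  null variance parameters only.
- No missing-data multivariate extensions: the multivariate scan is
  complete-case by construction.
- No random-effects meta-analysis or explicit sample-overlap
  correction beyond what the empirical V absorbs.
- The simulator's LD is blockwise-flat; there is no recombination-map
  realism, so LD-decay-dependent methods should not be benchmarked on
  it.
- Variant annotation (consequence prediction, candidate genes) is a
  pass-through hook, not computed.
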
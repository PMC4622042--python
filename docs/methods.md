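# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic data do and do not emulate. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Growth-curve stage

### Pre-adjustment of fixed effects

Raw weights carry management effects (contemporary group, birth year, farm)
that belong to the record, not to the animal's growth parameters. For each
age independently, `preadjust_fixed_effects` fits ordinary least squares of
weight on the named categorical factors (intercept + drop-first dummies) and
replaces each weight by *grand mean + residual*. The per-age grand mean is
preserved exactly (residuals of an intercept model sum to zero); a factor
level observed once is fitted exactly and contributes a zero residual. A
design with zero residual degrees of freedom (factor confounded with animal)
is an error rather than a silent identity.

### Models and fitting

Five weight–age functions are implemented with analytic Jacobians
(parameters A kg, b unitless, K per age unit, Richards exponent M):
Brody `A(1−be^{−Kt})`, von Bertalanffy `A(1−be^{−Kt})³`, Logistic
`A(1+be^{−Kt})^{−1}`, Gompertz `A·exp(−be^{−Kt})`, Richards
`A(1−be^{−Kt})^M` (minus-sign convention; a non-positive base is an error
since the power is generally non-integer).

Each animal is fitted independently — with six observations and three
parameters per animal there is little room for shrinkage to help, and
population summaries then have a transparent meaning as means/SDs of
independent estimates. Fitting is Gauss–Newton with a Levenberg–Marquardt
ladder: solve `(JᵀJ + λ·diag(JᵀJ))δ = Jᵀr`, accept only SSE-decreasing
steps, multiply λ by 10 per rejection (divide by 10 on acceptance, floor
1e−12, up to 30 rejections per outer iteration, 200 outer iterations).
Convergence requires the maximum relative parameter change of an accepted
step below 1e−8. Starting values: A₀ = 1.1 × max weight; b₀ solved from the
first observation given A₀ (clamped to ≥1e−6 when the closed form leaves
its domain); K₀ = SSE-argmin over the grid {0.005, 0.010, …, 0.5}; M₀ = 1.
Degenerate inputs — zero weight variance, non-finite Jacobians, a singular
system at every damping level — return `converged=False` without raising
and count against the convergence rate C%. A converged fit must have A > 0
and K > 0.

K's unit is the reciprocal of whatever age unit the records use; the
package never converts between monthly and daily scales.

### Goodness of fit and model choice

With n records, p parameters and residual sum of squares SSE:
`mse = SSE/(n−p)`, `r2_adj = 1 − mse/(SST/(n−1))`,
`aic = n·ln(SSE/n) + 2(p+1)` (Gaussian likelihood with σ estimated; SSE
floored at 1e−12 so perfect fits stay finite). MAD₁/MAD₂ are the mean
absolute residuals over the first ⌈n/2⌉ ages and the remaining ages — for
the 6-point cattle grid that is 0/6/12 vs 15/18/24 months, for the 5-point
simulated grid 3 early vs 2 late points. Model selection first drops models
with C% < 50 (a model that rarely converges is useless regardless of fit),
then ranks by criteria won (higher mean R², lower mean MSE, MAD₁, MAD₂,
AIC), ties broken by lower mean AIC — a deterministic rule.

## Pedigree and variance components

`build_a_matrix` uses Henderson's tabular method (dense, exact for acyclic
pedigrees, handles inbreeding through the diagonal); the GWAS then takes the
principal submatrix for phenotyped animals, which is the correct marginal
model and keeps the mixed-model system small. The recursive-coancestry
construction serves as the independent oracle in the tests.

`reml_null` estimates Σu, Σe for the 3-trait animal model with one mean per
trait. The phenotyped-subset relationship matrix is eigendecomposed once
(eigenvalues clipped at 0), phenotypes are rotated, and the likelihood
factorises into per-eigenvalue 3×3 problems. Traits are standardised
internally to unit variance — their natural scales differ by four orders of
magnitude and would otherwise ruin the conditioning of the update equations
— and the covariance matrices are back-transformed at the end. Each
iteration computes the guaranteed-monotone EM update and an
average-information (Newton) candidate; the AI candidate is projected to
the PSD cone (eigenvalue clipping at 0) and blended toward the EM update by
step-halving, and is accepted only when its restricted log-likelihood beats
the EM update's. The log-likelihood path is therefore non-decreasing by
construction and asserted at every step. Convergence: change in restricted
log-likelihood < 1e−8, cap 500 iterations (`converged=False` with the last
estimates beyond that). Final matrices are PSD-projected if needed and the
projection is flagged and logged. Heritabilities and genetic correlations
follow as `h² = σ²u/(σ²u+σ²e)` per trait and
`r_g = σu(j,k)/√(σ²u(j)σ²u(k))` (undefined → NaN when a genetic variance is
zero).

Genetic correlations whose true values sit near ±1 make Σu nearly singular;
at a few hundred effective families the REML estimates of such correlations
are noisy (Monte-Carlo SD ≈ 0.1) and can pile up at the boundary. The
acceptance workflow therefore averages replicate simulated datasets rather
than trusting one draw.

## Association scan

Variance components are estimated once under the null and held fixed for
every SNP (the standard two-stage approximation — re-estimating REML per
SNP changes essentially nothing at these sample sizes and is orders of
magnitude slower). Per SNP, the rotated 2k×2k GLS system (mean + dosage
effect per trait) is solved; precomputed per-eigenvalue inverse blocks make
the scan O(n·m). Missing genotypes are mean-imputed per SNP inside the scan
only (QC keeps explicit missingness); SNPs constant after imputation are
flagged untestable. Per-trait tests are Wald with a normal reference
(variance components treated as known); the joint test is the 3-df
chi-square of ŝᵀCov(ŝ)⁻¹ŝ.

Multiple testing: Benjamini–Hochberg step-up q-values (via
`statsmodels.stats.multitest`), significant iff q < 0.05 — the primary
rule. A separate flag marks raw p < 0.001; the two rules are reported side
by side and never silently conjoined, since their intended combination in
the source methodology is ambiguous. Variance shares
`V_i = 100·2p_i q_i ŝ_i²/Σ_j 2p_j q_j ŝ_j²` are normalised over the scanned
SNP set per trait (they sum to 100 whenever any effect is nonzero); an
all-zero denominator yields zeros with a warning.

QC order is fixed: individual call rate ≥ 0.95, SNP call rate ≥ 0.95,
MAF ≥ 0.01, then the two-sided exact Hardy–Weinberg test at P ≥ 1e−7
(probability-ordering exact test over all heterozygote counts compatible
with the allele counts, computed in log space).

## Linkage disequilibrium and blocks

Two-locus haplotype frequencies come from the standard EM over unphased
genotypes (double heterozygotes split by the current cis/trans odds;
tolerance 1e−10, cap 1000 iterations). D, D′ and r² follow from the
converged frequencies; both are invariant to allele-label swaps. The 90% CI
on |D′| profiles the multinomial genotype likelihood over a |D′| grid (step
0.005) with single-locus allele frequencies fixed at their estimates,
taking the 5th/95th cumulative-likelihood bounds; degenerate tables fall
back to a seeded 100-resample multinomial bootstrap.

Blocks use the D′-CI definition: a pair is *strong LD* iff CI-low ≥ 0.70
and CI-high ≥ 0.98, *strong recombination* iff CI-high < 0.9, otherwise
uninformative. A run of map-consecutive SNPs (span ≤ 500 kb by default,
configurable) is a block iff it has ≥1 informative pair and ≥95% of
informative pairs in strong LD; maximal non-overlapping blocks are chosen
greedily by bp span with leftmost tie-breaking — deterministic output.
r² is computed and reported alongside, but the block rule itself is the
D′-CI one. Block variance is the per-trait sum of member V_i; genome totals
per trait are emitted with it.

## Synthetic data

The generator reproduces exactly the structure the analysis assumes:
founder genotypes in Hardy–Weinberg proportions at per-SNP frequencies ~
U(0.1, 0.9); gametes by Mendelian transmission with Haldane recombination
over evenly spaced markers (1 Morgan mapped to 100 Mb, so 1 cM = 1 Mb);
per-animal parameters = population mean + Σ(dosage × QTL effect) +
pedigree polygenic deviation + independent parameter noise; weights =
curve + i.i.d. N(0, σ²) noise, floored at 0.1 kg. Polygenic deviations are
gene-dropped down the pedigree (founders draw the full Σu; non-founders are
the parent average plus a Mendelian deviation with variance
(0.5 − 0.25(F_s+F_d))Σu), which is exact for u ~ N(0, Σu⊗A). QTL are
snapped to the nearest existing SNP so a scan can hit them exactly; default
effects are 1.0 (large) and 0.2 (small) polygenic SDs, placed
deterministically across chromosomes.

**QTLMAS-like preset**: 100 full-sib families × 20 offspring, 453 SNPs on 5
chromosomes of 1 Morgan, logistic curves at days (0, 132, 265, 397, 530) —
the middle point is read as 265, completing the otherwise equal ~132-day
spacing — with phenotypes for a random half of the offspring (n = 1000).
Population parameters (A = 520 kg, b = 12, K = 0.0125/day) give a birth
weight of 40 kg and an inflection near 200 days; polygenic heritability is
0.3 per parameter with moderate genetic correlations (±0.3) and 8 kg weight
noise.

**Brahman-like stand-in** (labelled synthetic throughout): the real
weight–age file is not redistributable, so a hierarchical 50-sire ×
5-dam × 5-offspring population (1250 phenotyped animals) is generated *at*
the reported values — Brody means (520.32 kg, 0.92, 0.06/month),
heritabilities (0.23, 0.41, 0.31), genetic correlations (0.78, −0.84,
−0.88), phenotypic parameter SDs (50 kg, 0.015, 0.015) — plus planted
birth-year and farm effects (per-level × age offsets, SD 6 kg, centred per
age because only contrasts are identifiable; an uncentred average would act
as a jagged common offset that the curve fit amplifies into a
population-level parameter bias). Weight noise is nominal (0.3 kg): the
mature-weight estimate extrapolates beyond the 24-month record and
amplifies weight noise roughly twenty-fold on this grid, so realistic
weighing error would attenuate the recovered heritabilities — the stand-in
instead puts essentially all variability at the parameter level, which is
the level the recovery checks target. Consequently the stand-in's
*residual* diagnostics (MSE, MAD) are far smaller than a real herd's, and
passing them says nothing about fieldwork-scale measurement error.

What the generator does **not** emulate: founder LD beyond linkage,
selection, overlapping generations, genotyping error, dominance/epistasis,
age-dependent residual variance, or within-animal residual correlation
over time (the growth fits assume independence, matching the model class
implemented here).

### Permutation replicates

`permute_within_timepoint` shuffles raw weights across animals separately
per time point: marginals at each age are preserved exactly, factor levels
stay with the animal, and both the across-age dependence and the
genotype–phenotype link are destroyed — useful as a null device, tested as
such. For the *power* study, replicates must preserve each animal's genetic
signal, so `permute_residuals_within_timepoint` shuffles the residuals
around each animal's fitted curve within time points and re-adds them: new
noise realisations on intact individual trajectories. A raw shuffle would
drive detection power of true QTL to the false-positive floor, which
contradicts the purpose of a power validation; the residual shuffle is the
coherent reading and is what `qtlmas_power_study` uses.

## Problem sizes and seeds

All randomness flows from explicit integer seeds through numpy's seeded
generators; every public simulation op takes a seed and identical seeds are
bitwise reproducible. Sizes used by the shipped workflows (chosen to keep a
laptop run in minutes while leaving Monte-Carlo error well inside each
check's band): 20 replicate stand-ins for the genetic-parameter recovery
check (MC SE ≈ 0.026 on the correlations; 6 replicates in the acceptance
script's summary), 10 no-QTL replicates × 453 SNPs for scan calibration,
10 permuted replicates for power, 20 random parameter draws per model for
the noiseless-recovery property.

## Known limitations

* Per-animal least squares, not a nonlinear mixed model: no shrinkage
  across animals; parameter estimates for weakly determined animals (small
  K) are noisy, and A is an extrapolation beyond the last record.
* Two-stage scan: p-values ignore the uncertainty of Σu/Σe (standard, but
  slightly anticonservative at small n).
* Genetic correlations near ±1 are estimated with large sampling error and
  boundary pile-up at a-few-hundred-family scale.
* The X chromosome is treated as an ordinary label — no dosage
  compensation.
* Two-locus EM phasing only; no multi-locus haplotype inference or
  haplotype association tests.
* Gene annotation is a local nearest-gene lookup (≤1 Mb) against a
  user-supplied BED table; no database queries, homology search or
  enrichment analysis.
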
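# gcgwas — growth-curve-parameter GWAS

Association studies of body weight in livestock usually test one age at a
time. `gcgwas` instead treats the **whole growth trajectory** as the
phenotype: it fits a nonlinear growth model to each animal's weight–age
records, then uses the per-animal parameter estimates — mature weight *A*
(kg), the integration constant *b*, and maturity rate *K* (per age unit) — as
three correlated traits in a multi-trait, single-SNP mixed-model GWAS with a
pedigree polygenic effect. It is aimed at animal-breeding researchers who
want to map loci that change the *shape* of a growth curve, not just weight
at a fixed age.

## The model

**Growth stage.** Five classical weight–age functions are supported
(Brody, von Bertalanffy, Logistic, Gompertz, Richards); e.g. Brody:

```
w_t = A (1 − b e^{−Kt})
```

Each animal is fitted independently by Gauss–Newton nonlinear least squares
(Levenberg–Marquardt damping), after per-age ordinary-least-squares
pre-adjustment of the raw weights for categorical fixed effects
(contemporary group, birth year, farm). Models are compared on adjusted R²,
MSE, early/late-curve mean absolute deviations (MAD₁/MAD₂), AIC and the
convergence rate C%.

**Association stage.** For each SNP the three parameter estimates are
modelled jointly as

```
y = W s + Z u + e,     u ~ N(0, Σu ⊗ A),     e ~ N(0, Σe ⊗ I)
```

where **A** is the pedigree numerator relationship matrix (Henderson's
tabular method), **s** the SNP's 3-vector of allele-substitution effects
under 0/1/2 dosage coding, and Σu, Σe the 3×3 genetic and residual
covariance matrices. Σu and Σe are estimated once by REML under the no-SNP
model (eigen-rotated, monotone EM with average-information acceleration),
yielding heritabilities and genetic correlations; the scan then holds them
fixed and solves a generalized-least-squares system per SNP. Significance
uses per-trait Wald tests with Benjamini–Hochberg FDR (q < 0.05) plus a
3-df joint test; each SNP's share of marker-attributed genetic variance is

```
V_i = 100 · 2 p_i q_i ŝ_i² / Σ_j 2 p_j q_j ŝ_j²
```

and D′-confidence-interval (Gabriel-style) haplotype blocks aggregate ΣV_i
per region. A synthetic-data module simulates full-sib pedigrees, linked
SNPs (Haldane recombination), planted QTL and pedigree-structured polygenic
effects to validate QTL-detection power.

## Worked example

The package ships a synthetic stand-in for a ~1250-head beef-cattle
population (Brody growth, weights at 0–24 months, planted year/farm effects)
and a QTLMAS2009-like full-sib preset (100 families × 20 offspring, 453
SNPs on 5 chromosomes, logistic growth, 6 QTL per parameter):

```python
from gcgwas import workflows

study = workflows.brahman_growth_study(seed=1)
s = study.summary
print(f"animals fitted: {s.n_attempted}  convergence: {s.c_pct:.1f}%")
print(f"mean A = {s.param_means['A']:.2f} kg   "
      f"mean b = {s.param_means['b']:.3f}   "
      f"mean K = {s.param_means['K']:.4f} /month")

ps = workflows.qtlmas_power_study(seed=1, n_replicates=10)
print("large-QTL detection %:", {t: ps.large[t] for t in ("A", "b", "K")})
print("small-QTL detection %:", {t: round(ps.small_mean[t], 1) for t in ("A", "b", "K")})
```

prints

```
animals fitted: 1250  convergence: 100.0%
mean A = 521.19 kg   mean b = 0.921   mean K = 0.0591 /month
large-QTL detection %: {'A': 100.0, 'b': 100.0, 'K': 100.0}
small-QTL detection %: {'A': 20.0, 'b': 0.0, 'K': 0.0}
```

The fitted population means recover the stand-in's generating values
(A = 520.32 kg, b = 0.92, K = 0.06/month), every animal's 6-point fit
converges, and the planted large-effect QTL (1 genetic SD) is detected in
every permuted replicate while the small ones (0.2 SD) rarely clear the FDR
threshold — the expected power ordering for a 1000-animal scan.

A command-line interface wraps the same stages for file-based runs:

```sh
gcgwas simulate --preset qtlmas2009 --seed 1 --out-dir sim/
gcgwas fit  --phenotypes sim/phenotypes.csv --layout long --model logistic --out-dir fit/
gcgwas scan --fits fit/fits.tsv --pedigree sim/pedigree.csv \
            --genotypes sim/genotypes.tsv --map sim/map.tsv --out-dir scan/
gcgwas blocks --results scan/scan_results.tsv --genotypes sim/genotypes.tsv \
              --map sim/map.tsv --trait A --out-dir blocks/
gcgwas report --results scan/scan_results.tsv --out-dir report/
```

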
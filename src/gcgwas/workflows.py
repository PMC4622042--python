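"""End-to-end study workflows combining the pipeline stages.

These are the analyses the package exists for, bundled so that scripts and
tests run exactly the same code paths:

* ``brahman_growth_study``: pre-adjustment + per-animal Brody fits + the
  descriptive weight table on the synthetic Brahman-like stand-in.
* ``brahman_genetic_parameters``: 3-trait REML heritabilities and genetic
  correlations on (A-hat, b-hat, K-hat), averaged over replicate stand-ins.
* ``null_scan_calibration``: empirical per-trait type-I error of the
  multi-trait scan on no-QTL simulations.
* ``qtlmas_power_study``: QTL-detection power over permuted replicates of
  the QTLMAS2009-like preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_models import fit_population, preadjust_fixed_effects
from .kinship import build_a_matrix
from .mt_gwas import TraitMatrix, genetic_parameters, reml_null, snp_scan, trait_matrix_from_fits
from .reporting import PowerSummary, detection_power
from .synthetic_data import (
    permute_residuals_within_timepoint,
    qtlmas2009_config,
    simulate_brahman_like,
    simulate_families,
    simulate_growth_phenotypes,
    simulate_qtlmas2009,
)

TRAITS = ("A", "b", "K")


def descriptive_stats(phenos) -> pd.DataFrame:
    """Per-age n, mean, SD, min, max of the weights."""
    rows = []
    for s in phenos:
        for a, w in zip(s.ages, s.weights):
            rows.append((float(a), float(w)))
    df = pd.DataFrame(rows, columns=["age", "weight"])
    out = df.groupby("age")["weight"].agg(["count", "mean", "std", "min", "max"])
    return out.rename(columns={"count": "n", "std": "sd"}).reset_index()


@dataclass
class GrowthStudyResult:
    summary: object  # PopulationFitSummary for the Brody model
    fits: list
    stats: pd.DataFrame
    phenos: list
    pedigree: object


def brahman_growth_study(seed: int = 1) -> GrowthStudyResult:
    """Stand-in reproduction of the growth-curve stage: simulate the
    Brahman-like population, pre-adjust year/farm fixed effects, and fit the
    Brody model per animal."""
    _, ped, phenos, _ = simulate_brahman_like(seed=seed)
    stats = descriptive_stats(phenos)
    adjusted = preadjust_fixed_effects(phenos, ["birth_year", "farm_birth"])
    fits, summary = fit_population(adjusted, "brody")
    return GrowthStudyResult(summary, fits, stats, adjusted, ped)


def brahman_genetic_parameters(seed: int = 1, n_replicates: int = 3):
    """Mean REML heritabilities / genetic correlations over replicate
    stand-in populations (replicates average away the sampling noise a
    single ~1250-animal dataset would carry).

    Returns ``(h2, rg, per_replicate)`` with h2/rg dicts of means.
    """
    h2s, rgs = [], []
    for rep in range(n_replicates):
        study = brahman_growth_study(seed=seed + rep)
        y = trait_matrix_from_fits(study.fits)
        rel = build_a_matrix(study.pedigree)
        vc = reml_null(y, rel)
        gp = genetic_parameters(vc)
        h2s.append(gp.h2)
        rgs.append(gp.rg)
    h2 = {t: float(np.mean([h[t] for h in h2s])) for t in TRAITS}
    rg = {k: float(np.mean([r[k] for r in rgs])) for k in rgs[0]}
    return h2, rg, (h2s, rgs)


def null_scan_calibration(seed: int = 1, n_replicates: int = 10,
                          alpha: float = 0.05):
    """Empirical per-trait rejection rate of the scan under the null.

    Simulates the QTLMAS-like preset with no QTL, uses the true simulated
    parameters as phenotypes (isolating the scan's calibration from
    curve-fitting noise), and pools per-trait p-values over replicates.
    """
    rates = []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 + rep
        cfg, ped, geno, phenos, truth = simulate_qtlmas2009(
            seed=rep_seed, with_qtl=False)
        tp = truth.params
        y = TraitMatrix(list(tp.animal_id), tp[list(TRAITS)].to_numpy())
        rel = build_a_matrix(ped)
        vc = reml_null(y, rel)
        res = snp_scan(y, geno.subset_animals(y.animal_ids), vc, rel)
        for t in TRAITS:
            rates.append(float((res[f"p_{t}"] < alpha).mean()))
    return float(np.mean(rates)), rates


def qtlmas_power_study(seed: int = 1, n_replicates: int = 10,
                       window_bp: int = 5_000_000) -> PowerSummary:
    """QTL-detection power over permuted replicates of the QTLMAS preset.

    The base dataset is simulated once (with planted QTL); each replicate
    shuffles the residuals around the per-animal fitted logistic curves
    within every time point, refits, re-estimates variance components, and
    rescans. Detection = a per-trait BH-significant SNP within ``window_bp``
    (default 5 cM at the generator's 1 cM = 1 Mb scale) of the true QTL.
    """
    cfg, ped, geno, phenos, truth = simulate_qtlmas2009(seed=seed)
    base_fits, _ = fit_population(phenos, cfg.curve_model)
    rel = build_a_matrix(ped)
    results = []
    for rep in range(n_replicates):
        replicate = permute_residuals_within_timepoint(
            phenos, base_fits, seed=seed + 2000 + rep)
        fits, _ = fit_population(replicate, cfg.curve_model)
        y = trait_matrix_from_fits(fits)
        vc = reml_null(y, rel)
        results.append(snp_scan(y, geno.subset_animals(y.animal_ids), vc, rel))
    return detection_power(results, truth, window_bp=window_bp)
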
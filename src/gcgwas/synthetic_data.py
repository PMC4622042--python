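"""Simulation of pedigrees, genotypes, planted QTL and weight-age records.

The generator produces data with exactly the statistical structure the
analysis assumes: full-sib (or hierarchical) pedigrees; founder genotypes
in Hardy-Weinberg proportions at per-SNP allele frequencies drawn from
Uniform(0.1, 0.9); Mendelian gamete transmission with recombination via
Haldane's map function over evenly spaced markers; per-animal growth-curve
parameters composed of population means, additive QTL dosage effects, a
pedigree-structured polygenic deviation (gene dropping, exact for
Sigma_u (x) A), independent parameter noise, and i.i.d. residual noise on
the weights at fixed ages.

Two presets are provided:

* ``qtlmas2009``: 100 full-sib families x 20 offspring, 453 SNPs on 5
  chromosomes of 1 Morgan, logistic curves at 5 time points (days), 6 QTL
  per parameter (one large, five small); phenotypes available for half the
  offspring. The published time grid is read as (0, 132, 265, 397, 530)
  days (equal ~132-day spacing).
* ``brahman_like``: a SYNTHETIC stand-in for the real Brahman weight-age
  file (which is not redistributable here): ~1250 animals in a hierarchical
  sire/dam pedigree, Brody curves at (0, 6, 12, 15, 18, 24) months with
  population means A=520.32 kg, b=0.92, K=0.06/month, heritabilities
  (0.23, 0.41, 0.31) and genetic correlations (0.78, -0.84, -0.88) for
  (A,b), (A,K), (b,K), plus planted birth-year and farm fixed effects.

All randomness flows from a single integer seed; every public operation
takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PedigreeTable, WeightSeries
from .growth_models import get_model
from .io_formats import sort_pedigree
from .kinship import build_a_matrix

__all__ = [
    "QtlEffect", "SimConfig", "TruthRecord", "simulate_families",
    "simulate_growth_phenotypes", "permute_within_timepoint",
    "permute_residuals_within_timepoint", "qtlmas2009_config",
    "simulate_qtlmas2009", "brahman_like_config", "simulate_brahman_like",
]

#: physical scale of simulated maps: 1 Morgan = 100 Mb (1 cM = 1 Mb)
BP_PER_MORGAN = 100_000_000


@dataclass(frozen=True)
class QtlEffect:
    parameter: str  # "A", "b" or "K"
    chrom: int  # 1-based chromosome index
    pos_morgan: float
    effect: float  # additive allele-substitution effect, trait units


@dataclass
class SimConfig:
    n_families: int = 100
    offspring_per_family: int = 20
    n_snps: int = 453
    n_chromosomes: int = 5
    chromosome_length: float = 1.0  # Morgans
    time_points: tuple = (0.0, 132.0, 265.0, 397.0, 530.0)
    curve_model: str = "logistic"
    population_params: tuple = (520.0, 12.0, 0.0125)
    qtl_spec: list | None = None  # None -> default 1 large + 5 small per parameter
    polygenic_cov: np.ndarray = field(
        default_factory=lambda: np.diag([30.0, 1.0, 0.001]) ** 2
    )
    param_noise_sd: tuple = (45.8, 1.53, 0.00153)
    residual_sd: float = 8.0
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_families, self.offspring_per_family, self.n_snps,
               self.n_chromosomes) <= 0:
            raise ValueError("counts must be positive")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        cov = np.asarray(self.polygenic_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("polygenic_cov must be symmetric 3x3")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("polygenic_cov must be positive semidefinite")
        self.polygenic_cov = cov
        for q in self.qtl_spec or []:
            if not (0 <= q.pos_morgan <= self.chromosome_length):
                raise ValueError(f"QTL position {q.pos_morgan} outside chromosome")
            if not (1 <= q.chrom <= self.n_chromosomes):
                raise ValueError(f"QTL chromosome {q.chrom} out of range")


@dataclass
class TruthRecord:
    """Ground truth: per-animal true parameters and the planted QTL."""

    params: pd.DataFrame  # animal_id, A, b, K
    qtl: pd.DataFrame  # parameter, chrom, pos_morgan, bp, snp_id, effect


def default_qtl_spec(config: SimConfig) -> list[QtlEffect]:
    """One large (1.0 polygenic SD) and five small (0.2 SD) QTL per
    parameter, spread deterministically over the chromosomes."""
    sds = np.sqrt(np.diag(np.asarray(config.polygenic_cov, dtype=float)))
    L = config.chromosome_length
    spec = []
    for j, param in enumerate(("A", "b", "K")):
        chrom_large = (j % config.n_chromosomes) + 1
        spec.append(QtlEffect(param, chrom_large, 0.5 * L, 1.0 * sds[j]))
        for s in range(5):
            chrom = ((j + 1 + s) % config.n_chromosomes) + 1
            pos = (0.15 + 0.15 * s) * L
            spec.append(QtlEffect(param, chrom, pos, 0.2 * sds[j]))
    return spec


def _snp_map(config: SimConfig):
    """Evenly spaced markers: chromosome c gets m_c SNPs at (i+0.5) L/m_c."""
    base, extra = divmod(config.n_snps, config.n_chromosomes)
    counts = [base + (1 if c < extra else 0) for c in range(config.n_chromosomes)]
    chroms, pos_m = [], []
    for c, m in enumerate(counts, start=1):
        step = config.chromosome_length / m
        for i in range(m):
            chroms.append(str(c))
            pos_m.append((i + 0.5) * step)
    return np.array(chroms, dtype=object), np.array(pos_m)


def _recomb_probs(chroms, pos_m):
    """Haldane recombination fraction between adjacent markers; chromosome
    starts get r = 0.5 (independent assortment)."""
    r = np.empty(len(pos_m))
    r[0] = 0.5
    for j in range(1, len(pos_m)):
        if chroms[j] != chroms[j - 1]:
            r[j] = 0.5
        else:
            d = pos_m[j] - pos_m[j - 1]
            r[j] = 0.5 * (1.0 - np.exp(-2.0 * d))
    return r


def _gametes(haps, n, r, rng):
    """Draw n gametes from a (2, m) phased parent by Markov recombination."""
    switches = rng.random((n, len(r))) < r[None, :]
    which = np.cumsum(switches, axis=1) % 2
    return np.where(which == 0, haps[0][None, :], haps[1][None, :])


def simulate_families(config: SimConfig, seed: int | None = None):
    """Simulate full-sib families: pedigree plus phased-then-collapsed
    genotypes for parents and offspring.

    Founder haplotype alleles are independent Bernoulli draws at per-SNP
    frequencies ~ Uniform(0.1, 0.9); offspring gametes recombine between
    adjacent markers with Haldane's map function.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 101])
    chroms, pos_m = _snp_map(config)
    m = len(pos_m)
    r = _recomb_probs(chroms, pos_m)
    freqs = rng.uniform(0.1, 0.9, size=m)

    ids, sires, dams = [], [], []
    geno_ids, codes = [], []
    for f in range(1, config.n_families + 1):
        sire_id, dam_id = f"S{f:03d}", f"D{f:03d}"
        sire_h = (rng.random((2, m)) < freqs).astype(np.int8)
        dam_h = (rng.random((2, m)) < freqs).astype(np.int8)
        for pid, h in ((sire_id, sire_h), (dam_id, dam_h)):
            ids.append(pid)
            sires.append(None)
            dams.append(None)
            geno_ids.append(pid)
            codes.append(h.sum(axis=0))
        n_off = config.offspring_per_family
        pat = _gametes(sire_h, n_off, r, rng)
        mat = _gametes(dam_h, n_off, r, rng)
        off = (pat + mat).astype(np.int8)
        for o in range(n_off):
            oid = f"F{f:03d}_O{o + 1:02d}"
            ids.append(oid)
            sires.append(sire_id)
            dams.append(dam_id)
            geno_ids.append(oid)
            codes.append(off[o])
    ped = sort_pedigree(ids, sires, dams)
    bp = np.round(pos_m * BP_PER_MORGAN).astype(np.int64) + 1
    snp_ids = [f"snp{c}_{i}" for i, c in enumerate(chroms, start=1)]
    geno = GenotypeMatrix(geno_ids, snp_ids, np.array(codes, dtype=np.int8),
                          chroms, bp)
    return ped, geno


def _snap_qtl(config: SimConfig, geno: GenotypeMatrix) -> pd.DataFrame:
    """Place each QTL on the nearest existing SNP of its chromosome."""
    spec = config.qtl_spec if config.qtl_spec is not None else default_qtl_spec(config)
    rows = []
    for q in spec:
        sel = np.flatnonzero(geno.chrom == str(q.chrom))
        if len(sel) == 0:
            raise ValueError(f"no SNPs on chromosome {q.chrom}")
        bp_target = q.pos_morgan * BP_PER_MORGAN
        j = sel[int(np.argmin(np.abs(geno.bp[sel] - bp_target)))]
        rows.append({
            "parameter": q.parameter, "chrom": str(q.chrom),
            "pos_morgan": q.pos_morgan, "bp": int(geno.bp[j]),
            "snp_id": geno.snp_ids[j], "effect": q.effect,
        })
    return pd.DataFrame(rows,
                        columns=["parameter", "chrom", "pos_morgan", "bp",
                                 "snp_id", "effect"])


def _drop_polygenic(ped: PedigreeTable, cov: np.ndarray, rng) -> np.ndarray:
    """Gene-drop a multivariate polygenic effect down the pedigree.

    Exact for u ~ N(0, cov (x) A): founders draw the full covariance, and
    each non-founder is the parent average plus a Mendelian-sampling
    deviation with variance (0.5 - 0.25 (F_s + F_d)) cov.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    w, Q = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        raise ValueError("polygenic covariance must be positive semidefinite")
    L = Q * np.sqrt(np.clip(w, 0, None))
    n = len(ped)
    F = build_a_matrix(ped).inbreeding()
    idx = ped.index_of()
    Z = rng.standard_normal((n, k))
    u = np.zeros((n, k))
    for i, (s, d) in enumerate(zip(ped.sires, ped.dams)):
        si = idx[s] if s is not None else -1
        di = idx[d] if d is not None else -1
        # Mendelian sampling variance: 1 - 0.25(1+F_s) - 0.25(1+F_d) per
        # known parent; an unknown parent contributes as an unrelated founder.
        mean = np.zeros(k)
        ms = 1.0
        if si >= 0:
            mean += 0.5 * u[si]
            ms -= 0.25 * (1.0 + F[si])
        if di >= 0:
            mean += 0.5 * u[di]
            ms -= 0.25 * (1.0 + F[di])
        u[i] = mean + np.sqrt(max(ms, 0.0)) * (Z[i] @ L.T)
    return u


def simulate_growth_phenotypes(ped: PedigreeTable, geno: GenotypeMatrix | None,
                               config: SimConfig, seed: int | None = None,
                               animal_subset: list | None = None):
    """Simulate weight-age records and return (phenotypes, truth).

    Per-animal parameters are population mean + QTL dosages x effects +
    pedigree polygenic deviation + independent parameter noise; weights are
    the growth-curve prediction at the configured time points plus
    N(0, residual_sd^2) noise (floored at 0.1 kg).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 202])
    if geno is not None:
        missing = set(geno.animal_ids) - set(ped.animal_ids)
        if missing:
            raise ValueError(f"genotyped animals not in pedigree: "
                             f"{sorted(missing)[:5]}")
    spec = get_model(config.curve_model)
    mu = np.asarray(config.population_params, dtype=float)[:3]

    u = _drop_polygenic(ped, config.polygenic_cov, rng)
    noise_sd = np.asarray(config.param_noise_sd, dtype=float)
    eps = rng.standard_normal((len(ped), 3)) * noise_sd[None, :]

    idx = ped.index_of()
    if animal_subset is None:
        animal_subset = list(geno.animal_ids) if geno is not None else list(ped.animal_ids)

    if geno is not None:
        qtl = _snap_qtl(config, geno)
        snp_pos = geno.snp_index()
        gidx = {a: i for i, a in enumerate(geno.animal_ids)}
    else:
        qtl = pd.DataFrame(columns=["parameter", "chrom", "pos_morgan", "bp",
                                    "snp_id", "effect"])

    t = np.asarray(config.time_points, dtype=float)
    phenos, rows = [], []
    param_col = {"A": 0, "b": 1, "K": 2}
    for aid in animal_subset:
        theta = mu + u[idx[aid]] + eps[idx[aid]]
        if geno is not None and len(qtl):
            dose = geno.codes[gidx[aid]]
            for q in qtl.itertuples(index=False):
                theta[param_col[q.parameter]] += dose[snp_pos[q.snp_id]] * q.effect
        full = theta
        if spec.n_params == 4:
            full = np.append(theta, 1.0)
        w = spec.predict(full, t)
        w = w + rng.standard_normal(len(t)) * config.residual_sd
        w = np.maximum(w, 0.1)
        phenos.append(WeightSeries(aid, t.copy(), w))
        rows.append({"animal_id": aid, "A": theta[0], "b": theta[1],
                     "K": theta[2]})
    truth = TruthRecord(pd.DataFrame(rows), qtl)
    return phenos, truth


# ---------------------------------------------------------------------------
# permutation replicates
# ---------------------------------------------------------------------------

def _check_shared_grid(phenos):
    t0 = phenos[0].ages
    for s in phenos[1:]:
        if len(s.ages) != len(t0) or not np.array_equal(s.ages, t0):
            raise ValueError("all series must share identical time points")
    return t0


def permute_within_timepoint(phenos, seed: int):
    """Shuffle the raw weights across animals, separately per time point.

    The multiset of weights at each time point is preserved exactly; factor
    levels stay with the animal. Destroys both the genotype-phenotype link
    and the within-animal correlation across time points.
    """
    phenos = list(phenos)
    t0 = _check_shared_grid(phenos)
    rng = np.random.default_rng([int(seed), 303])
    W = np.array([s.weights for s in phenos])
    for j in range(len(t0)):
        W[:, j] = W[rng.permutation(len(phenos)), j]
    return [WeightSeries(s.animal_id, s.ages.copy(), W[i], dict(s.factors),
                         complete=s.complete)
            for i, s in enumerate(phenos)]


def permute_residuals_within_timepoint(phenos, fits, seed: int):
    """Replicate scheme that keeps each animal's own growth signal.

    Residuals around each animal's fitted curve are shuffled across animals
    within every time point and re-added to the fitted values, producing a
    new noise realisation while preserving the individual (and hence
    genetic) curve differences — the property the raw within-time-point
    shuffle destroys.
    """
    phenos = list(phenos)
    t0 = _check_shared_grid(phenos)
    rng = np.random.default_rng([int(seed), 404])
    fit_by_id = {f.animal_id: f for f in fits}
    pred = np.empty((len(phenos), len(t0)))
    for i, s in enumerate(phenos):
        f = fit_by_id[s.animal_id]
        pred[i] = get_model(f.model).predict(f.params, t0)
    resid = np.array([s.weights for s in phenos]) - pred
    for j in range(len(t0)):
        resid[:, j] = resid[rng.permutation(len(phenos)), j]
    W = np.maximum(pred + resid, 0.1)
    return [WeightSeries(s.animal_id, s.ages.copy(), W[i], dict(s.factors),
                         complete=s.complete)
            for i, s in enumerate(phenos)]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def qtlmas2009_config(seed: int = 1, with_qtl: bool = True) -> SimConfig:
    """QTLMAS2009-like preset: 100 full-sib families x 20 offspring, 453
    SNPs on 5 chromosomes of 1 Morgan, logistic growth at 5 time points
    (days), 6 QTL per parameter (one large = 1 polygenic SD, five small =
    0.2 SD). Heritability of each parameter from the polygenic component
    alone is 0.3."""
    sds = np.array([30.0, 1.0, 0.001])
    R = np.array([[1.0, 0.3, -0.3], [0.3, 1.0, -0.3], [-0.3, -0.3, 1.0]])
    cov = (sds[:, None] * R) * sds[None, :]
    env = tuple(np.round(sds * np.sqrt(0.7 / 0.3), 6))
    cfg = SimConfig(
        n_families=100, offspring_per_family=20, n_snps=453, n_chromosomes=5,
        chromosome_length=1.0, time_points=(0.0, 132.0, 265.0, 397.0, 530.0),
        curve_model="logistic", population_params=(520.0, 12.0, 0.0125),
        polygenic_cov=cov, param_noise_sd=env, residual_sd=8.0, seed=seed,
    )
    if not with_qtl:
        cfg = replace(cfg, qtl_spec=[])
    return cfg


def simulate_qtlmas2009(seed: int = 1, with_qtl: bool = True):
    """Full QTLMAS2009-like dataset: phenotypes (and analysis genotypes) for
    a random half of the offspring (n = 1000), genotypes for everyone.

    Returns ``(config, ped, geno, phenos, truth)``.
    """
    cfg = qtlmas2009_config(seed=seed, with_qtl=with_qtl)
    ped, geno = simulate_families(cfg, seed=seed)
    offspring = [a for a, s in zip(ped.animal_ids, ped.sires) if s is not None]
    rng = np.random.default_rng([int(seed), 505])
    half = sorted(rng.choice(len(offspring), size=len(offspring) // 2,
                             replace=False))
    analysed = [offspring[i] for i in half]
    phenos, truth = simulate_growth_phenotypes(ped, geno, cfg, seed=seed,
                                               animal_subset=analysed)
    return cfg, ped, geno, phenos, truth


def _centered_effects(levels, ages, sd, rng):
    eff = rng.normal(0.0, sd, size=(len(levels), len(ages)))
    eff -= eff.mean(axis=0, keepdims=True)
    return {(lev, a): eff[i, j] for i, lev in enumerate(levels)
            for j, a in enumerate(ages)}


def brahman_like_config(seed: int = 1) -> SimConfig:
    """SYNTHETIC stand-in for the Brahman weight-age study population.

    Brody curves at (0, 6, 12, 15, 18, 24) months with population means
    A = 520.32 kg, b = 0.92, K = 0.06 per month; parameter heritabilities
    (0.23, 0.41, 0.31) and genetic correlations r_g(A,b) = 0.78,
    r_g(A,K) = -0.84, r_g(b,K) = -0.88; phenotypic parameter SDs
    (50 kg, 0.015, 0.015) and nominal (0.3 kg) residual weight noise.
    """
    sd_p = np.array([50.0, 0.015, 0.015])
    h2 = np.array([0.23, 0.41, 0.31])
    Rg = np.array([[1.0, 0.78, -0.84], [0.78, 1.0, -0.88], [-0.84, -0.88, 1.0]])
    sg = np.sqrt(h2) * sd_p
    cov = (sg[:, None] * Rg) * sg[None, :]
    env = tuple(np.sqrt((1.0 - h2)) * sd_p)
    return SimConfig(
        n_families=250, offspring_per_family=5, n_snps=100, n_chromosomes=5,
        chromosome_length=1.0, time_points=(0.0, 6.0, 12.0, 15.0, 18.0, 24.0),
        curve_model="brody", population_params=(520.32, 0.92, 0.06),
        qtl_spec=[], polygenic_cov=cov, param_noise_sd=env, residual_sd=0.3,
        seed=seed,
    )


def simulate_brahman_like(seed: int = 1, n_sires: int = 50,
                          dams_per_sire: int = 5, offspring_per_dam: int = 5):
    """Hierarchical sire/dam pedigree stand-in (default 1250 offspring).

    Offspring carry planted birth-year and farm fixed effects (level x age
    offsets, SD 6 kg) so the fixed-effect pre-adjustment step has real work
    to do. Returns ``(config, ped, phenos, truth)``; no genotypes (the
    association stage of the study ran on a proprietary SNP chip, so this
    stand-in only supports the growth-curve and variance-component stages).
    """
    cfg = brahman_like_config(seed=seed)
    rng = np.random.default_rng([int(seed), 606])
    ids, sires, dams = [], [], []
    for s in range(1, n_sires + 1):
        ids.append(f"SIRE{s:03d}")
        sires.append(None)
        dams.append(None)
    off_ids = []
    for s in range(1, n_sires + 1):
        for d in range(1, dams_per_sire + 1):
            dam_id = f"DAM{s:03d}_{d}"
            ids.append(dam_id)
            sires.append(None)
            dams.append(None)
            for o in range(1, offspring_per_dam + 1):
                oid = f"C{s:03d}_{d}_{o}"
                ids.append(oid)
                sires.append(f"SIRE{s:03d}")
                dams.append(dam_id)
                off_ids.append(oid)
    ped = sort_pedigree(ids, sires, dams)
    phenos, truth = simulate_growth_phenotypes(ped, None, cfg, seed=seed,
                                               animal_subset=off_ids)

    years = [str(y) for y in range(2004, 2011)]
    farms = [f"FARM{i}" for i in range(1, 6)]
    t = np.asarray(cfg.time_points)
    # level effects are centered per age: only contrasts are identifiable, and
    # a nonzero per-age average would act as a jagged common offset that the
    # growth fit amplifies into a population-level parameter bias
    year_eff = _centered_effects(years, t, 6.0, rng)
    farm_eff = _centered_effects(farms, t, 6.0, rng)
    out = []
    for s in phenos:
        y = years[rng.integers(len(years))]
        f = farms[rng.integers(len(farms))]
        w = s.weights + np.array([year_eff[(y, a)] + farm_eff[(f, a)]
                                  for a in s.ages])
        w = np.maximum(w, 0.1)
        factors = {"breed": "Brahman", "birth_year": y, "farm_birth": f,
                   "farm_reloc": farms[rng.integers(len(farms))]}
        out.append(WeightSeries(s.animal_id, s.ages.copy(), w, factors))
    return cfg, ped, out, truth
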
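"""Multi-trait single-SNP mixed-model GWAS on growth-curve parameters.

The phenotypes are the per-animal growth-curve parameter estimates
(A, b, K). The model for the trait vector of animal i at SNP j is

    y = W s + Z u + e,    u ~ N(0, Sigma_u (x) A),    e ~ N(0, Sigma_e (x) I)

with A the pedigree numerator relationship matrix, Sigma_u / Sigma_e the
3x3 genetic and residual covariance matrices, and s the SNP's 3-vector of
additive allele-substitution effects on (A, b, K) under 0/1/2 dosage coding.

Estimation is two-stage: Sigma_u and Sigma_e are estimated once by REML
under the null (no-SNP) model, then held fixed for a generalized
least-squares scan of every SNP (the standard fixed-variance-component
approximation). The REML solver eigendecomposes the phenotyped-subset
relationship matrix once, rotates the phenotypes so observations decouple
into per-eigenvalue 3x3 problems, and runs monotone EM iterations with an
average-information (Newton-type) accelerated step that is accepted only
when it improves the restricted likelihood.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MISSING, TRAITS, GenotypeMatrix
from .kinship import RelationshipMatrix, subset

log = logging.getLogger("gcgwas")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TraitMatrix:
    """Animals x traits phenotype block (no missing cells)."""

    animal_ids: list[str]
    values: np.ndarray  # (n, k)
    trait_names: tuple = TRAITS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.animal_ids):
            raise ValueError("trait matrix shape mismatch")
        if self.values.shape[1] != len(self.trait_names):
            raise ValueError("trait name count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait matrix contains non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def trait_matrix_from_fits(fits) -> TraitMatrix:
    """Assemble (A, b, K) phenotypes from converged growth fits."""
    ids, rows = [], []
    for f in fits:
        if not f.converged:
            continue
        ids.append(f.animal_id)
        rows.append([f.param("A"), f.param("b"), f.param("K")])
    if not ids:
        raise ValueError("no converged fits to build a trait matrix from")
    return TraitMatrix(ids, np.array(rows))


@dataclass
class VarianceComponents:
    sigma_u: np.ndarray  # (k, k) genetic covariance
    sigma_e: np.ndarray  # (k, k) residual covariance
    loglik: float
    converged: bool
    n_iter: int
    projected: bool = False
    loglik_path: list = field(default_factory=list, repr=False)
    trait_names: tuple = TRAITS


@dataclass
class GeneticParameters:
    h2: dict  # trait -> heritability
    rg: dict  # (trait_a, trait_b) -> genetic correlation


class QCError(ValueError):
    def __init__(self, message, report):
        super().__init__(message)
        self.report = report


@dataclass
class QCReport:
    n_animals_in: int
    n_snps_in: int
    animals_removed_call: list
    snps_removed_call: list
    snps_removed_maf: list
    snps_removed_hwe: list

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - len(self.animals_removed_call)

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - len(self.snps_removed_call)
                - len(self.snps_removed_maf) - len(self.snps_removed_hwe))


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Frequency of the allele coded 2: p = (2 n2 + n1) / (2 n_called).

    Fully missing SNPs get NaN (flagged undefined).
    """
    codes = geno.codes
    called = codes != MISSING
    n_called = called.sum(axis=0)
    dose = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose / (2.0 * np.maximum(n_called, 1)), np.nan)
    return p


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts (compatible with the
    observed allele counts) whose conditional probability does not exceed
    that of the observed count. Zero total or a monomorphic SNP returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_a = 2 * n_hom1 + n_het  # count of the rarer-or-not allele 1
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    logp = np.array([
        h * math.log(2.0)
        - lg(h + 1) - lg((n_a - h) / 2 + 1) - lg((n_b - h) / 2 + 1)
        for h in hets
    ])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(geno: GenotypeMatrix, thresholds: dict | None = None):
    """Filter genotypes: individual call rate, SNP call rate, MAF, HWE.

    Defaults mirror the study's thresholds: call rates >= 0.95, MAF >= 0.01,
    HWE exact P >= 1e-7. Returns the filtered matrix and a :class:`QCReport`
    counting removals at each step; raises :class:`QCError` (report attached)
    if no SNP survives.
    """
    th = {"ind_call": 0.95, "snp_call": 0.95, "maf": 0.01, "hwe_p": 1e-7}
    if thresholds:
        th.update(thresholds)
    for k, v in th.items():
        if not (0 <= v <= 1):
            raise ValueError(f"threshold {k} outside [0, 1]")

    codes = geno.codes
    called = codes != MISSING

    ind_rate = called.mean(axis=1)
    keep_a = ind_rate >= th["ind_call"]
    animals_removed = [a for a, k_ in zip(geno.animal_ids, keep_a) if not k_]
    codes = codes[keep_a]
    called = called[keep_a]

    snp_rate = called.mean(axis=0) if codes.shape[0] else np.zeros(codes.shape[1])
    keep_call = snp_rate >= th["snp_call"]
    removed_call = [s for s, k_ in zip(geno.snp_ids, keep_call) if not k_]

    n_called = np.where(called, 1, 0).sum(axis=0)
    dose = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose / (2.0 * np.maximum(n_called, 1)), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = keep_call & (maf >= th["maf"])
    removed_maf = [s for s, kc, km in zip(geno.snp_ids, keep_call, keep_maf)
                   if kc and not km]

    keep = keep_maf.copy()
    removed_hwe = []
    for j in np.flatnonzero(keep_maf):
        col = codes[:, j]
        col = col[col != MISSING]
        pval = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                              int((col == 2).sum()))
        if pval < th["hwe_p"]:
            keep[j] = False
            removed_hwe.append(geno.snp_ids[j])

    report = QCReport(geno.n_animals, geno.n_snps, animals_removed,
                      removed_call, removed_maf, removed_hwe)
    if not keep.any():
        raise QCError("all SNPs removed by QC", report)
    kept_animals = [a for a, k_ in zip(geno.animal_ids, keep_a) if k_]
    out = GenotypeMatrix(
        kept_animals, [s for s, k_ in zip(geno.snp_ids, keep) if k_],
        codes[:, keep], geno.chrom[keep], geno.bp[keep],
        [al for al, k_ in zip(geno.alleles, keep)] if geno.alleles else None,
    )
    return out, report


# ---------------------------------------------------------------------------
# REML for the multi-trait animal model
# ---------------------------------------------------------------------------

def _rotate(y: TraitMatrix, rel: RelationshipMatrix):
    """Eigendecompose the phenotyped-subset A and rotate phenotypes."""
    missing = set(y.animal_ids) - set(rel.ids)
    if missing:
        raise ValueError(f"animals missing from relationship matrix: "
                         f"{sorted(missing)[:5]}")
    A = subset(rel, y.animal_ids).values
    d, U = linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    ystar = U.T @ y.values
    x0 = U.T @ np.ones(y.n)
    return d, U, ystar, x0


def _stack_inv(d, sigma_u, sigma_e):
    V = d[:, None, None] * sigma_u[None] + sigma_e[None]
    return np.linalg.inv(V), V


def _gls_quantities(d, x0, ystar, sigma_u, sigma_e):
    """Per-eigenvalue GLS pieces for the mean-only fixed effects."""
    Vinv, V = _stack_inv(d, sigma_u, sigma_e)
    B = np.einsum("n,nij->ij", x0 * x0, Vinv)
    rhs = np.einsum("n,nij,nj->i", x0, Vinv, ystar)
    C = np.linalg.inv(B)
    beta = C @ rhs
    R = ystar - np.outer(x0, beta)
    t = np.einsum("nij,nj->ni", Vinv, R)
    sign, logdetV = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        return None
    signB, logdetB = np.linalg.slogdet(B)
    ll = -0.5 * (logdetV.sum() + float(np.sum(R * t)) + logdetB)
    return {"Vinv": Vinv, "C": C, "beta": beta, "R": R, "t": t, "ll": ll}


def _reml_loglik(d, x0, ystar, sigma_u, sigma_e) -> float:
    q = _gls_quantities(d, x0, ystar, sigma_u, sigma_e)
    return -np.inf if q is None else q["ll"]


def _is_psd(M, tol=-1e-8) -> bool:
    return bool(np.linalg.eigvalsh(0.5 * (M + M.T)).min() >= tol)


def _psd_project(M: np.ndarray) -> np.ndarray:
    """Nearest (Frobenius) PSD matrix: eigenvalue clipping at 0."""
    M = 0.5 * (M + M.T)
    w, Q = np.linalg.eigh(M)
    if w.min() >= 0:
        return M
    return (Q * np.clip(w, 0.0, None)) @ Q.T


def _vech_bases(k):
    pairs = [(i, i) for i in range(k)] + [
        (i, j) for i in range(k) for j in range(i + 1, k)
    ]
    bases = []
    for i, j in pairs:
        E = np.zeros((k, k))
        E[i, j] = E[j, i] = 1.0
        bases.append(E)
    return pairs, bases


def reml_null(y: TraitMatrix, rel: RelationshipMatrix, max_iter: int = 500,
              tol: float = 1e-8) -> VarianceComponents:
    """REML of Sigma_u and Sigma_e for the null (no-SNP) animal model.

    Fixed effects are one overall mean per trait. The restricted
    log-likelihood is non-decreasing across iterations by construction: the
    average-information candidate step is accepted only when it improves it
    (with step-halving toward the guaranteed-monotone EM update otherwise).
    """
    if y.n < 30:
        raise ValueError("reml_null needs at least 30 animals")
    k = y.k
    # standardize traits so the working covariances are O(1): trait scales in
    # this problem differ by orders of magnitude (kg^2 vs ~1e-4), which would
    # otherwise destroy the conditioning of the average-information system
    scale = np.std(y.values, axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    y = TraitMatrix(y.animal_ids, y.values / scale[None, :], y.trait_names)
    d, _, ystar, x0 = _rotate(y, rel)
    n = y.n

    S = np.cov(y.values, rowvar=False)
    S = np.atleast_2d(S) + 1e-8 * np.eye(k) * max(np.trace(np.atleast_2d(S)), 1.0)
    sigma_u, sigma_e = 0.5 * S, 0.5 * S

    pairs, bases = _vech_bases(k)
    n_par = len(pairs)
    path = []
    converged = False
    it = 0
    q = _gls_quantities(d, x0, ystar, sigma_u, sigma_e)
    for it in range(1, max_iter + 1):
        ll = q["ll"]
        path.append(ll)
        Vinv, C, t = q["Vinv"], q["C"], q["t"]
        VCV = np.einsum("nab,bc,ncd->nad", Vinv, C, Vinv)
        Pii = Vinv - (x0 * x0)[:, None, None] * VCV
        Diff = np.einsum("ni,nj->nij", t, t) - Pii
        Du = np.einsum("n,nij->ij", d, Diff)
        De = Diff.sum(axis=0)

        # guaranteed-monotone EM update
        su_em = sigma_u + sigma_u @ Du @ sigma_u / n
        se_em = sigma_e + sigma_e @ De @ sigma_e / n
        su_em = 0.5 * (su_em + su_em.T)
        se_em = 0.5 * (se_em + se_em.T)

        # average-information candidate: projected to PSD and blended toward
        # the EM update by step-halving; accepted only if it beats EM (which
        # itself never decreases the likelihood), so monotonicity holds
        cand = _ai_candidate(d, x0, ystar, sigma_u, sigma_e, q, Du, De,
                             pairs, bases, n_par)
        ll_em = _reml_loglik(d, x0, ystar, su_em, se_em)
        new = (su_em, se_em)
        if cand is not None:
            su_ai, se_ai = cand
            for frac in (1.0, 0.5, 0.25):
                su_c = _psd_project(frac * su_ai + (1 - frac) * su_em)
                se_c = _psd_project(frac * se_ai + (1 - frac) * se_em)
                ll_c = _reml_loglik(d, x0, ystar, su_c, se_c)
                if ll_c >= ll_em:
                    new = (su_c, se_c)
                    break
        sigma_u, sigma_e = new
        q = _gls_quantities(d, x0, ystar, sigma_u, sigma_e)
        ll_new = q["ll"] if q is not None else -np.inf
        if ll_new < ll - 1e-6 * max(1.0, abs(ll)):
            raise AssertionError(
                f"restricted log-likelihood decreased: {ll} -> {ll_new}"
            )
        if abs(ll_new - ll) < tol:
            converged = True
            path.append(ll_new)
            break

    projected = False
    for name, M in (("sigma_u", sigma_u), ("sigma_e", sigma_e)):
        w, Q = np.linalg.eigh(0.5 * (M + M.T))
        if w.min() < 0:
            projected = True
            log.info("PSD projection applied to %s (min eigenvalue %.3g)",
                     name, w.min())
            M[:] = (Q * np.clip(w, 0, None)) @ Q.T
    # back-transform to the original trait scales
    D = np.diag(scale)
    sigma_u = D @ sigma_u @ D
    sigma_e = D @ sigma_e @ D
    loglik = _reml_loglik(d, x0, ystar * scale[None, :], sigma_u, sigma_e)
    return VarianceComponents(sigma_u, sigma_e, loglik, converged, it,
                              projected, path, tuple(y.trait_names))


def _ai_candidate(d, x0, ystar, sigma_u, sigma_e, q, Du, De, pairs, bases,
                  n_par):
    """One average-information Newton step on vech(Sigma_u), vech(Sigma_e)."""
    Vinv, C, t = q["Vinv"], q["C"], q["t"]
    k = sigma_u.shape[0]
    score = np.empty(n_par * 2)
    for m, (i, j) in enumerate(pairs):
        su = Du[i, j] if i == j else Du[i, j] + Du[j, i]
        se = De[i, j] if i == j else De[i, j] + De[j, i]
        score[m] = 0.5 * su
        score[n_par + m] = 0.5 * se
    # v vectors: (dV/dtheta) t per observation
    Et = [t @ E.T for E in bases]  # E symmetric -> E t_i
    vs = [d[:, None] * et for et in Et] + Et  # Sigma_u then Sigma_e params
    Vv = [np.einsum("nij,nj->ni", Vinv, v) for v in vs]
    a = [np.einsum("n,ni->i", x0, vv) for vv in Vv]
    P = len(vs)
    AI = np.empty((P, P))
    for mi in range(P):
        for mj in range(mi, P):
            val = 0.5 * (float(np.sum(vs[mi] * Vv[mj])) - a[mi] @ C @ a[mj])
            AI[mi, mj] = AI[mj, mi] = val
    try:
        step = np.linalg.solve(AI + 1e-10 * np.eye(P), score)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(step)):
        return None
    su_new, se_new = sigma_u.copy(), sigma_e.copy()
    for m, (i, j) in enumerate(pairs):
        su_new[i, j] += step[m]
        su_new[j, i] = su_new[i, j]
        se_new[i, j] += step[n_par + m]
        se_new[j, i] = se_new[i, j]
    return su_new, se_new


def genetic_parameters(vc: VarianceComponents) -> GeneticParameters:
    """Heritabilities h2_j and genetic correlations r_g(j, l).

    h2_j = var_u(j) / (var_u(j) + var_e(j)); traits with zero genetic
    variance get an undefined (NaN) correlation.
    """
    names = vc.trait_names
    su, se = vc.sigma_u, vc.sigma_e
    h2 = {}
    for j, nm in enumerate(names):
        tot = su[j, j] + se[j, j]
        h2[nm] = float(su[j, j] / tot) if tot > 0 else float("nan")
    rg = {}
    for j in range(len(names)):
        for l in range(j + 1, len(names)):
            denom = math.sqrt(max(su[j, j], 0.0) * max(su[l, l], 0.0))
            rg[(names[j], names[l])] = (
                float(su[j, l] / denom) if denom > 0 else float("nan")
            )
    return GeneticParameters(h2, rg)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def snp_scan(y: TraitMatrix, geno: GenotypeMatrix, vc: VarianceComponents,
             rel: RelationshipMatrix, alpha: float = 0.05,
             p_threshold: float = 0.001) -> pd.DataFrame:
    """Single-SNP multi-trait GLS scan with variance components held fixed.

    For every SNP the fixed effects are one mean per trait plus the SNP
    dosage effect per trait; the 2k x 2k GLS system is solved on the rotated
    (eigen-decorrelated) scale. Missing genotypes are mean-imputed per SNP
    for the scan only. Per-trait Wald tests use the normal reference; the
    joint test is a k-df chi-square. Per-trait BH q-values, the secondary
    raw p < ``p_threshold`` flag, and per-trait variance shares V_i are
    appended.
    """
    k = y.k
    d, U, ystar, x0 = _rotate(y, rel)
    geno_sub = geno.subset_animals(y.animal_ids)
    Vinv, _ = _stack_inv(d, vc.sigma_u, vc.sigma_e)
    g = np.einsum("nij,nj->ni", Vinv, ystar)
    S00 = np.einsum("n,nij->ij", x0 * x0, Vinv)
    r0 = np.einsum("n,ni->i", x0, g)

    codes = geno_sub.codes.astype(float)
    miss = geno_sub.codes == MISSING
    freqs = allele_frequencies(geno_sub)
    col_mean = np.where(np.isnan(freqs), 0.0, 2.0 * freqs)
    W = np.where(miss, col_mean[None, :], codes)
    testable = W.std(axis=0) > 0
    Wstar = U.T @ W

    X2 = Wstar ** 2
    S11_all = np.einsum("nm,nij->mij", X2, Vinv)
    S01_all = np.einsum("nm,nij->mij", Wstar * x0[:, None], Vinv)
    r1_all = np.einsum("nm,ni->mi", Wstar, g)

    m = geno_sub.n_snps
    effects = np.full((m, k), np.nan)
    ses = np.full((m, k), np.nan)
    p_traits = np.full((m, k), np.nan)
    p_joint = np.full(m, np.nan)
    for j in range(m):
        if not testable[j]:
            continue
        M = np.empty((2 * k, 2 * k))
        M[:k, :k] = S00
        M[:k, k:] = S01_all[j]
        M[k:, :k] = S01_all[j]
        M[k:, k:] = S11_all[j]
        rhs = np.concatenate([r0, r1_all[j]])
        try:
            cov = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        beta = cov @ rhs
        s = beta[k:]
        cov_ss = cov[k:, k:]
        se = np.sqrt(np.diag(cov_ss))
        effects[j] = s
        ses[j] = se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = s / se
        p_traits[j] = 2.0 * stats.norm.sf(np.abs(z))
        try:
            chi2 = float(s @ np.linalg.solve(cov_ss, s))
            p_joint[j] = stats.chi2.sf(chi2, df=k)
        except np.linalg.LinAlgError:
            pass

    p_traits = np.clip(p_traits, np.nextafter(0, 1), 1.0)
    p_joint = np.clip(p_joint, np.nextafter(0, 1), 1.0)

    out = {"snp_id": geno_sub.snp_ids, "chrom": geno_sub.chrom,
           "bp": geno_sub.bp, "freq": freqs}
    names = list(y.trait_names)
    for jt, nm in enumerate(names):
        out[f"s_{nm}"] = effects[:, jt]
        out[f"se_{nm}"] = ses[:, jt]
        out[f"p_{nm}"] = np.where(testable, p_traits[:, jt], np.nan)
    out["p_joint"] = np.where(testable, p_joint, np.nan)
    df = pd.DataFrame(out)
    for jt, nm in enumerate(names):
        qv, sig, raw = bh_fdr(df[f"p_{nm}"].to_numpy(), alpha=alpha,
                              p_threshold=p_threshold)
        df[f"q_{nm}"] = qv
        df[f"sig_{nm}"] = sig
        df[f"raw_{nm}"] = raw
        df[f"V_{nm}"] = variance_explained(
            np.where(testable, effects[:, jt], 0.0), freqs
        )
    df["untestable"] = ~testable
    return df


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05,
           p_threshold: float = 0.001):
    """Benjamini-Hochberg step-up q-values with significance flags.

    Returns ``(q, significant, raw_flag)`` where ``significant`` is
    q < alpha (the primary rule) and ``raw_flag`` marks raw p < p_threshold
    (the secondary rule, reported separately, never conjoined silently).
    NaN p-values (untestable SNPs) propagate as NaN / False.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] <= 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        rej, qv, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        sig[ok] = qv < alpha
    raw = np.zeros(p.shape, dtype=bool)
    raw[ok] = p[ok] < p_threshold
    return q, sig, raw


def variance_explained(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP share of the marker-attributed genetic variance, in percent:

        V_i = 100 * 2 p_i q_i s_i^2 / sum_j 2 p_j q_j s_j^2

    with the denominator taken over all scanned SNPs of the trait. An
    all-zero denominator yields all-zero shares with a warning.
    """
    effects = np.asarray(effects, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if effects.shape != p.shape:
        raise ValueError("effects and freqs must align")
    pq = np.where(np.isnan(p), 0.0, p * (1.0 - p))
    contrib = 2.0 * pq * np.where(np.isfinite(effects), effects, 0.0) ** 2
    total = contrib.sum()
    if total <= 0:
        warnings.warn("all SNP effects zero: variance shares set to 0",
                      stacklevel=2)
        return np.zeros_like(contrib)
    return 100.0 * contrib / total


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
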
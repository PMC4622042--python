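"""Pairwise linkage disequilibrium and Gabriel-style haplotype blocks.

Haplotype frequencies for a pair of biallelic SNPs are estimated from
unphased 0/1/2 genotypes by the standard two-locus EM (double heterozygotes
split between the two phases by their current relative likelihood). D' and
r^2 come from the converged frequencies; the 90% confidence interval on |D'|
is obtained by profiling the multinomial genotype likelihood over a |D'|
grid with the single-locus allele frequencies held at their estimates (the
Haploview construction), with a seeded bootstrap fallback for degenerate
tables. Blocks follow the D'-CI definition: runs of SNPs in which at least
95% of informative pairs are in strong LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, chrom_sort_key

__all__ = ["LdEstimate", "HaploBlock", "pairwise_ld", "gabriel_blocks",
           "block_variance", "blocks_to_frame"]


@dataclass
class LdEstimate:
    snp_a: str
    snp_b: str
    r2: float
    d_prime: float
    ci_low: float
    ci_high: float
    n: int  # informative animals (called on both SNPs)
    converged: bool = True


@dataclass
class HaploBlock:
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list
    variance: dict = field(default_factory=dict)  # trait -> sum of V_i


def _pair_table(geno: GenotypeMatrix, ia: int, ib: int):
    a = geno.codes[:, ia]
    b = geno.codes[:, ib]
    ok = (a != MISSING) & (b != MISSING)
    tab = np.zeros((3, 3))
    for ga, gb in zip(a[ok], b[ok]):
        tab[ga, gb] += 1
    return tab, int(ok.sum())


def _em_haplotypes(tab: np.ndarray, max_iter: int = 1000, tol: float = 1e-10):
    """EM haplotype frequencies (f00, f01, f10, f11) from a 3x3 count table.

    Index 1 refers to the allele coded 2 at each locus.
    """
    n = tab.sum()
    pa = (tab[1].sum() + 2 * tab[2].sum()) / (2 * n)
    pb = (tab[:, 1].sum() + 2 * tab[:, 2].sum()) / (2 * n)
    f = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    dh = tab[1, 1]  # double heterozygotes: phase ambiguous
    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        c00 = (2 * tab[0, 0] + tab[0, 1] + tab[1, 0] + w * dh)
        c01 = (2 * tab[0, 2] + tab[0, 1] + tab[1, 2] + (1 - w) * dh)
        c10 = (2 * tab[2, 0] + tab[1, 0] + tab[2, 1] + (1 - w) * dh)
        c11 = (2 * tab[2, 2] + tab[2, 1] + tab[1, 2] + w * dh)
        f_new = np.array([c00, c01, c10, c11]) / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return f, converged


def _d_stats(f):
    pa = f[2] + f[3]
    pb = f[1] + f[3]
    D = f[3] - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = D * D / denom if denom > 0 else 0.0
    return pa, pb, D, min(d_prime, 1.0), min(r2, 1.0)


def _genotype_class_probs(f):
    """3x3 genotype probabilities under random union of haplotypes."""
    H = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    P = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            ga = H[i, 0] + H[j, 0]
            gb = H[i, 1] + H[j, 1]
            P[ga, gb] += f[i] * f[j]
    return P


def _dprime_ci(tab, pa, pb, sign_positive, grid_step=0.005):
    """Profile-likelihood 90% CI on |D'| with allele frequencies fixed."""
    if not sign_positive:
        tab = tab[:, ::-1]  # swap allele labels at locus B -> D becomes >= 0
        pb = 1.0 - pb
    dmax = min(pa * (1 - pb), (1 - pa) * pb)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    logl = np.full(grid.shape, -np.inf)
    for gidx, dp in enumerate(grid):
        f11 = pa * pb + dp * dmax
        f = np.array([
            (1 - pa) * (1 - pb) + dp * dmax,
            (1 - pa) * pb - dp * dmax,
            pa * (1 - pb) - dp * dmax,
            f11,
        ])
        if np.any(f < -1e-9):
            continue
        f = np.clip(f, 1e-12, None)
        f /= f.sum()
        P = np.clip(_genotype_class_probs(f), 1e-300, None)
        logl[gidx] = float(np.sum(tab * np.log(P)))
    finite = np.isfinite(logl)
    if not finite.any():
        return None
    like = np.zeros_like(logl)
    like[finite] = np.exp(logl[finite] - logl[finite].max())
    total = like.sum()
    if total <= 0:
        return None
    csum = np.cumsum(like) / total
    low = grid[int(np.argmax(csum >= 0.05))]
    tail = 1.0 - np.concatenate([[0.0], csum[:-1]])
    high = grid[int(np.max(np.flatnonzero(tail >= 0.05)))]
    return float(low), float(high)


def pairwise_ld(geno: GenotypeMatrix, snp_a: str, snp_b: str,
                max_iter: int = 1000, seed: int = 0) -> LdEstimate:
    """LD between two SNPs: r^2, |D'| and its 90% CI.

    Requires both SNPs polymorphic and >= 20 animals called on both.
    """
    idx = geno.snp_index()
    ia, ib = idx[snp_a], idx[snp_b]
    tab, n = _pair_table(geno, ia, ib)
    if n < 20:
        raise ValueError(f"pair ({snp_a}, {snp_b}): only {n} animals called on both")
    for name, margin in ((snp_a, tab.sum(axis=1)), (snp_b, tab.sum(axis=0))):
        hom_only = margin[1] == 0 and (margin[0] == 0 or margin[2] == 0)
        if hom_only:
            raise ValueError(f"SNP {name} is monomorphic in the called subset")
    f, converged = _em_haplotypes(tab, max_iter=max_iter)
    pa, pb, D, d_prime, r2 = _d_stats(f)
    ci = _dprime_ci(tab, pa, pb, sign_positive=D >= 0)
    if ci is None:
        ci = _bootstrap_ci(tab, seed=seed)
    low, high = ci
    return LdEstimate(snp_a, snp_b, r2, d_prime, low, high, n, converged)


def _bootstrap_ci(tab, n_boot: int = 100, seed: int = 0):
    """Seeded multinomial bootstrap of |D'| (fallback for degenerate tables)."""
    rng = np.random.default_rng(seed)
    n = int(tab.sum())
    probs = (tab / n).ravel()
    vals = []
    for _ in range(n_boot):
        resampled = rng.multinomial(n, probs).reshape(3, 3).astype(float)
        f, _ = _em_haplotypes(resampled, max_iter=200)
        vals.append(_d_stats(f)[3])
    return float(np.percentile(vals, 5)), float(np.percentile(vals, 95))


def gabriel_blocks(geno: GenotypeMatrix, ci_low: float = 0.70,
                   ci_high: float = 0.98, strong_frac: float = 0.95,
                   recomb_high: float = 0.9,
                   max_span_bp: int = 500_000,
                   snp_subset: list | None = None) -> list[HaploBlock]:
    """Detect haplotype blocks by the D'-confidence-interval definition.

    A pair is *strong LD* iff its CI satisfies lower >= ``ci_low`` and upper
    >= ``ci_high``; *strong recombination* iff upper < ``recomb_high``; other
    pairs are uninformative. A candidate run of map-consecutive SNPs is a
    block iff it spans at most ``max_span_bp``, has at least one informative
    pair, and the strong-LD fraction among informative pairs is at least
    ``strong_frac``. Maximal non-overlapping blocks are chosen greedily by bp
    span, ties to the leftmost.
    """
    if snp_subset is not None:
        keep = [s in set(snp_subset) for s in geno.snp_ids]
        keep = np.array(keep)
        geno = GenotypeMatrix(
            geno.animal_ids, [s for s, k in zip(geno.snp_ids, keep) if k],
            geno.codes[:, keep], geno.chrom[keep], geno.bp[keep],
        )
    blocks: list[HaploBlock] = []
    for chrom in sorted(pd.unique(geno.chrom), key=chrom_sort_key):
        sel = np.flatnonzero(geno.chrom == chrom)
        m = len(sel)
        if m < 2:
            continue
        # pair classification: +1 strong LD, -1 strong recombination, 0 n/a
        cls = np.zeros((m, m), dtype=np.int8)
        for i in range(m):
            for j in range(i + 1, m):
                if geno.bp[sel[j]] - geno.bp[sel[i]] > max_span_bp:
                    continue
                try:
                    est = pairwise_ld(geno, geno.snp_ids[sel[i]],
                                      geno.snp_ids[sel[j]])
                except ValueError:
                    continue
                if est.ci_low >= ci_low and est.ci_high >= ci_high:
                    cls[i, j] = 1
                elif est.ci_high < recomb_high:
                    cls[i, j] = -1
        candidates = []
        for i in range(m):
            for j in range(i + 1, m):
                span = int(geno.bp[sel[j]] - geno.bp[sel[i]])
                if span > max_span_bp:
                    break
                sub = cls[i:j + 1, i:j + 1]
                n_strong = int((sub == 1).sum())
                n_inform = n_strong + int((sub == -1).sum())
                if n_inform == 0:
                    continue
                if n_strong / n_inform >= strong_frac:
                    candidates.append((span, i, j))
        candidates.sort(key=lambda c: (-c[0], c[1]))
        used = np.zeros(m, dtype=bool)
        for span, i, j in candidates:
            if used[i:j + 1].any():
                continue
            used[i:j + 1] = True
            blocks.append(HaploBlock(
                str(chrom), int(geno.bp[sel[i]]), int(geno.bp[sel[j]]),
                [geno.snp_ids[s] for s in sel[i:j + 1]],
            ))
    blocks.sort(key=lambda b: (chrom_sort_key(b.chrom), b.start_bp))
    return blocks


def block_variance(blocks: list[HaploBlock], snp_results: pd.DataFrame):
    """Fill each block's per-trait variance share (sum of member V_i).

    Returns ``(blocks, totals)`` where ``totals`` maps trait -> summed share
    over all blocks. Raises ``KeyError`` naming the first member SNP absent
    from the scan results.
    """
    v_cols = [c for c in snp_results.columns if c.startswith("V_")]
    table = snp_results.set_index("snp_id")[v_cols]
    totals = {c[2:]: 0.0 for c in v_cols}
    for blk in blocks:
        for s in blk.snp_ids:
            if s not in table.index:
                raise KeyError(f"block member SNP {s!r} missing from scan results")
        sub = table.loc[blk.snp_ids]
        blk.variance = {c[2:]: float(sub[c].sum()) for c in v_cols}
        for trait, val in blk.variance.items():
            totals[trait] += val
    return blocks, totals


def blocks_to_frame(blocks: list[HaploBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        row = {"chrom": b.chrom, "start_bp": b.start_bp, "end_bp": b.end_bp,
               "n_snps": len(b.snp_ids), "snp_ids": ",".join(b.snp_ids)}
        for trait, val in b.variance.items():
            row[f"V_{trait}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
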
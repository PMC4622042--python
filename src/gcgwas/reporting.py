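"""Nearest-gene annotation, plots, and QTL-detection power summaries."""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import MISSING, GeneTable, GenotypeMatrix, chrom_sort_key
from .growth_models import get_model
from .synthetic_data import TruthRecord

__all__ = ["GeneHit", "PowerSummary", "nearest_genes", "render_plots",
           "detection_power"]


@dataclass
class GeneHit:
    snp_id: str
    gene_id: str
    distance: int  # signed bp; 0 if the SNP lies inside the gene


@dataclass
class PowerSummary:
    """Per-parameter detection percentages over simulation replicates."""

    large: dict  # trait -> percent of replicates detecting the large QTL
    small_mean: dict  # trait -> mean percent over the five small QTL
    per_qtl: pd.DataFrame  # parameter, snp_id, effect_class, detection_pct
    n_replicates: int


def nearest_genes(snps: pd.DataFrame, genes: GeneTable,
                  max_dist: int = 1_000_000) -> list[GeneHit]:
    """All genes within ``max_dist`` bp of each SNP, nearest first.

    The distance is 0 for a SNP inside a gene, positive when the gene lies
    downstream (gene start > SNP), negative upstream. Equidistant genes are
    both reported, in gene-id order. Output is independent of the input
    gene-table ordering (GeneTable sorts on construction).
    """
    hits: list[GeneHit] = []
    gframe = genes.frame
    for snp in snps.itertuples(index=False):
        sub = gframe[gframe["chrom"].astype(str) == str(snp.chrom)]
        rows = []
        for g in sub.itertuples(index=False):
            if g.start <= snp.bp <= g.end:
                dist = 0
            elif snp.bp < g.start:
                dist = int(g.start - snp.bp)
            else:
                dist = int(g.end - snp.bp)  # negative: gene upstream of SNP
            if abs(dist) <= max_dist:
                rows.append((abs(dist), g.gene_id, dist))
        rows.sort(key=lambda r: (r[0], r[1]))
        hits.extend(GeneHit(snp.snp_id, gid, dist) for _, gid, dist in rows)
    return hits


def gene_hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [{"snp_id": h.snp_id, "gene_id": h.gene_id, "distance": h.distance}
         for h in hits],
        columns=["snp_id", "gene_id", "distance"],
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def render_plots(results: pd.DataFrame, fits=None, out_dir=".",
                 geno: GenotypeMatrix | None = None,
                 marker_id: str | None = None, alpha: float = 0.05,
                 ages: np.ndarray | None = None) -> list:
    """Write Manhattan and QQ plots per trait, and optionally the
    per-genotype growth-curve plot for one marker.

    Manhattan plots show -log10 q per SNP with chromosomes alternately
    coloured and a line at the significance threshold; QQ plots compare
    observed against uniform-expected -log10 p. The genotype-curve plot
    evaluates the growth model at the within-genotype-class means of the
    fitted parameters.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traits = [c[2:] for c in results.columns if c.startswith("q_")]
    written = []

    order = sorted(pd.unique(results["chrom"]), key=chrom_sort_key)
    offsets, ticks = {}, []
    pos = 0
    for c in order:
        sub = results[results["chrom"] == c]
        offsets[c] = pos - sub["bp"].min()
        ticks.append((str(c), pos + (sub["bp"].max() - sub["bp"].min()) / 2))
        pos += sub["bp"].max() - sub["bp"].min() + 1

    for trait in traits:
        fig, ax = plt.subplots(figsize=(9, 3))
        for i, c in enumerate(order):
            sub = results[results["chrom"] == c]
            q = sub[f"q_{trait}"].to_numpy(float)
            x = sub["bp"].to_numpy(float) + offsets[c]
            with np.errstate(divide="ignore"):
                y = -np.log10(np.clip(q, 1e-300, None))
            ax.scatter(x, y, s=6, color=("C0" if i % 2 == 0 else "C1"))
        ax.axhline(-np.log10(alpha), color="red", lw=0.8, ls="--")
        ax.set_xticks([t[1] for t in ticks])
        ax.set_xticklabels([t[0] for t in ticks], fontsize=7)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10}$ q")
        ax.set_title(f"Manhattan: {trait}")
        path = out_dir / f"manhattan_{trait}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

        p = results[f"p_{trait}"].dropna().to_numpy(float)
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        if len(p):
            obs = -np.log10(np.sort(p))
            exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
            ax.scatter(exp[::-1], obs[::-1], s=6)
            lim = max(exp.max(), obs.max())
            ax.plot([0, lim], [0, lim], color="red", lw=0.8)
        ax.set_xlabel(r"expected $-\log_{10}$ p")
        ax.set_ylabel(r"observed $-\log_{10}$ p")
        ax.set_title(f"QQ: {trait}")
        path = out_dir / f"qq_{trait}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if marker_id is not None:
        if geno is None or fits is None:
            raise ValueError("genotype-curve plot needs geno and fits")
        if marker_id not in geno.snp_ids:
            raise ValueError(f"unknown marker {marker_id!r}")
        written.append(
            _genotype_curve_plot(fits, geno, marker_id, out_dir, ages)
        )
    return written


def genotype_class_params(fits, geno: GenotypeMatrix, marker_id: str):
    """Mean fitted parameters per genotype class (0/1/2) at one marker."""
    j = geno.snp_index()[marker_id]
    dose = dict(zip(geno.animal_ids, geno.codes[:, j]))
    by_class: dict[int, list] = {0: [], 1: [], 2: []}
    model = None
    for f in fits:
        if not f.converged or f.animal_id not in dose:
            continue
        c = int(dose[f.animal_id])
        if c == MISSING:
            continue
        model = f.model
        by_class[c].append(f.params)
    return model, {c: np.mean(v, axis=0) for c, v in by_class.items() if v}


def _genotype_curve_plot(fits, geno, marker_id, out_dir, ages):
    model, means = genotype_class_params(fits, geno, marker_id)
    if ages is None:
        ages = np.linspace(0, 24, 100)
    spec = get_model(model)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    labels = {0: "hom. 1st allele", 1: "heterozygote", 2: "hom. 2nd allele"}
    for c, params in sorted(means.items()):
        ax.plot(ages, spec.predict(params, np.asarray(ages, float)),
                label=f"{labels[c]} (n-class {c})")
    ax.set_xlabel("age")
    ax.set_ylabel("weight (kg)")
    ax.set_title(f"{spec.name} curves by genotype at {marker_id}")
    ax.legend(fontsize=7)
    path = out_dir / f"genotype_curves_{marker_id}.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# detection power
# ---------------------------------------------------------------------------

def detection_power(replicate_results: list, truth: TruthRecord,
                    window_bp: int = 5_000_000, alpha: float = 0.05,
                    sig_prefix: str = "sig_") -> PowerSummary:
    """Percentage of replicates in which each planted QTL is detected.

    A QTL is detected in a replicate iff at least one SNP significant for
    the corresponding parameter (per-trait BH q < alpha flag in the scan
    output) lies within ``window_bp`` of the QTL position on the same
    chromosome. Reported separately for the large-effect QTL and averaged
    over the small ones (effect classes split at the per-parameter maximum
    |effect|).
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if not replicate_results:
        raise ValueError("need at least one replicate")
    qtl = truth.qtl.copy()
    if qtl.empty:
        raise ValueError("truth contains no QTL")
    qtl["abs_eff"] = qtl["effect"].abs()
    qtl["is_large"] = False
    for param, grp in qtl.groupby("parameter"):
        qtl.loc[grp["abs_eff"].idxmax(), "is_large"] = True

    n_rep = len(replicate_results)
    det_counts = np.zeros(len(qtl))
    for res in replicate_results:
        for qi, q in enumerate(qtl.itertuples(index=False)):
            col = f"{sig_prefix}{q.parameter}"
            if col not in res.columns:
                raise ValueError(f"scan results lack column {col!r}")
            sig = res[res[col].fillna(False).astype(bool)]
            sig = sig[sig["chrom"].astype(str) == str(q.chrom)]
            if len(sig) and (np.abs(sig["bp"].to_numpy() - q.bp) <= window_bp).any():
                det_counts[qi] += 1

    qtl["detection_pct"] = 100.0 * det_counts / n_rep
    qtl["effect_class"] = np.where(qtl["is_large"], "large", "small")
    large, small = {}, {}
    for param, grp in qtl.groupby("parameter"):
        large[param] = float(grp.loc[grp["is_large"], "detection_pct"].mean())
        sm = grp.loc[~grp["is_large"], "detection_pct"]
        small[param] = float(sm.mean()) if len(sm) else float("nan")
    per_qtl = qtl[["parameter", "snp_id", "effect_class", "detection_pct"]]
    return PowerSummary(large, small, per_qtl.reset_index(drop=True), n_rep)
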
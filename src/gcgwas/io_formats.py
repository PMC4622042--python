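"""Readers and writers for the external file formats, plus run configuration.

Supported files
---------------
* phenotype CSV, ``s1_wide`` dialect (one row per animal: id, sire, dam,
  breed, birth date parts, farm codes, one weight column per age) or ``long``
  (one row per animal x age);
* pedigree CSV (animal_id, sire, dam; 0/empty = unknown);
* genotype ``tsv012`` (animals x SNPs of 0/1/2/NA) or ``plink_raw``
  (PLINK ``--recode A`` style header + dosage columns) with a SNP map TSV;
* gene table BED (0-based half-open, converted to 1-based inclusive on read);
* YAML run configuration.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MISSING,
    GeneTable,
    GenotypeMatrix,
    PedigreeTable,
    WeightSeries,
    chrom_sort_key,
)

log = logging.getLogger("gcgwas")

#: default age grid (months) of the cattle weight records
DEFAULT_AGES = (0.0, 6.0, 12.0, 15.0, 18.0, 24.0)

_WIDE_FACTORS = (
    "sire", "dam", "breed", "birth_year", "birth_month", "birth_day",
    "farm_birth", "farm_reloc",
)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, layout: str = "s1_wide", ages=DEFAULT_AGES):
    """Read weight-age phenotypes into a list of :class:`WeightSeries`.

    ``s1_wide`` expects one row per animal with weight columns ``wt<age>``
    (e.g. ``wt0, wt6, wt12, wt15, wt18, wt24``); any metadata column is kept
    as a fixed-effect factor level. Animals missing any expected weight are
    returned with ``complete=False``; downstream steps keep complete records
    only, mirroring the study design (only 6-point animals analysed).

    ``long`` expects columns ``animal_id, age, weight`` plus optional factor
    columns (constant within animal).
    """
    path = Path(path)
    if layout == "s1_wide":
        return _read_wide(path, ages)
    if layout == "long":
        return _read_long(path)
    raise ValueError(f"unknown phenotype layout {layout!r}")


def _read_wide(path: Path, ages) -> list[WeightSeries]:
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if "animal_id" not in df.columns:
        raise ValueError(f"{path}: wide layout requires an 'animal_id' column")
    wt_cols = [_wt_col(a) for a in ages]
    missing_cols = [c for c in wt_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing weight columns {missing_cols}")
    factor_cols = [c for c in df.columns if c != "animal_id" and c not in wt_cols]

    out: dict[str, WeightSeries] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        aid = rec["animal_id"]
        if aid is None or (isinstance(aid, float) and np.isnan(aid)):
            raise ValueError(f"{path}:{pos}: malformed row (no animal id)")
        obs_ages, obs_wts = [], []
        for a, c in zip(ages, wt_cols):
            raw = rec[c]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue
            try:
                w = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{pos}: malformed weight {raw!r}") from exc
            obs_ages.append(float(a))
            obs_wts.append(w)
        factors = {c: ("" if pd.isna(rec[c]) else str(rec[c])) for c in factor_cols}
        series = WeightSeries(
            str(aid), np.array(obs_ages), np.array(obs_wts), factors,
            complete=len(obs_ages) == len(ages),
        )
        if series.animal_id in out:
            prev = out[series.animal_id]
            if (len(prev) != len(series)
                    or not np.array_equal(prev.ages, series.ages)
                    or not np.allclose(prev.weights, series.weights)):
                raise ValueError(
                    f"{path}:{pos}: duplicate animal {series.animal_id!r} "
                    "with conflicting weights"
                )
            continue
        out[series.animal_id] = series
    return list(out.values())


def _read_long(path: Path) -> list[WeightSeries]:
    df = pd.read_csv(path)
    for col in ("animal_id", "age", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: long layout requires column {col!r}")
    factor_cols = [c for c in df.columns if c not in ("animal_id", "age", "weight")]
    out = []
    for aid, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("age")
        if grp["age"].duplicated().any():
            dup = grp.loc[grp["age"].duplicated(), "age"].iloc[0]
            if grp.groupby("age")["weight"].nunique().max() > 1:
                raise ValueError(
                    f"{path}: duplicate animal {aid!r} with conflicting "
                    f"weights at age {dup}"
                )
            grp = grp.drop_duplicates("age")
        factors = {c: str(grp[c].iloc[0]) for c in factor_cols}
        out.append(
            WeightSeries(str(aid), grp["age"].to_numpy(float),
                         grp["weight"].to_numpy(float), factors)
        )
    return out


def write_phenotypes(phenos, path, layout: str = "long") -> None:
    """Write a collection of :class:`WeightSeries` (complete or not)."""
    path = Path(path)
    if layout == "long":
        rows = []
        for s in phenos:
            for a, w in zip(s.ages, s.weights):
                rows.append({"animal_id": s.animal_id, "age": a, "weight": w,
                             **s.factors})
        pd.DataFrame(rows).to_csv(path, index=False)
    elif layout == "s1_wide":
        rows = []
        for s in phenos:
            row = {"animal_id": s.animal_id, **s.factors}
            for a, w in zip(s.ages, s.weights):
                row[_wt_col(a)] = w
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown phenotype layout {layout!r}")


def _wt_col(age) -> str:
    age = float(age)
    return f"wt{age:g}"


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column pedigree CSV and return it topologically sorted.

    Unknown parents may be encoded as ``0`` or empty. Raises on cycles,
    listing the offending animals.
    """
    df = pd.read_csv(path, dtype=str, header=0)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs 3 columns (animal, sire, dam)")
    df = df.iloc[:, :3]
    df.columns = ["animal_id", "sire", "dam"]

    def _norm(v):
        if v is None or pd.isna(v) or str(v).strip() in ("", "0", ".", "NA"):
            return None
        return str(v)

    animals = [str(a) for a in df["animal_id"]]
    sires = [_norm(v) for v in df["sire"]]
    dams = [_norm(v) for v in df["dam"]]
    return sort_pedigree(animals, sires, dams)


def sort_pedigree(animals, sires, dams) -> PedigreeTable:
    """Topologically sort pedigree records parents-first (stable)."""
    known = set(animals)
    parents = {}
    for a, s, d in zip(animals, sires, dams):
        parents[a] = [p for p in (s, d) if p is not None and p in known]
        for p in (s, d):
            if p is not None and p not in known:
                # parent without own record: treat as founder, prepend
                parents.setdefault(p, [])
    ts = graphlib.TopologicalSorter(parents)
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as exc:
        raise ValueError(f"pedigree contains a cycle: {exc.args[1]}") from exc
    rec = {a: (s, d) for a, s, d in zip(animals, sires, dams)}
    ids, ss, dd = [], [], []
    for a in order:
        s, d = rec.get(a, (None, None))
        ids.append(a)
        ss.append(s)
        dd.append(d)
    return PedigreeTable(ids, ss, dd)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.to_frame().fillna("0")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(geno_path, map_path, dialect: str = "tsv012") -> GenotypeMatrix:
    """Read a dosage genotype matrix plus its SNP map.

    ``tsv012``: TSV, first column ``animal_id``, one column per SNP with cells
    0/1/2/NA.  ``plink_raw``: PLINK ``--recode A`` output (space-delimited,
    FID IID PAT MAT SEX PHENOTYPE then ``<snp>_<allele>`` dosage columns).
    The map TSV has columns ``snp_id, chrom, bp``; SNPs are returned sorted by
    (chromosome, bp).
    """
    if dialect == "tsv012":
        df = pd.read_csv(geno_path, sep="\t", dtype=str)
        if df.columns[0] != "animal_id":
            raise ValueError(f"{geno_path}: first column must be 'animal_id'")
        animals = [str(a) for a in df.iloc[:, 0]]
        snp_ids = list(df.columns[1:])
        codes = _parse_codes(df.iloc[:, 1:], geno_path)
        alleles = None
    elif dialect == "plink_raw":
        df = pd.read_csv(geno_path, sep=r"\s+", dtype=str)
        meta = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
        if not set(meta).issubset(df.columns):
            raise ValueError(f"{geno_path}: not a PLINK RAW header")
        animals = [str(a) for a in df["IID"]]
        snp_cols = [c for c in df.columns if c not in meta]
        snp_ids, alleles = [], []
        for c in snp_cols:
            sid, _, a2 = c.rpartition("_")
            snp_ids.append(sid if sid else c)
            alleles.append(("?", a2 if sid else "?"))
        codes = _parse_codes(df[snp_cols], geno_path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    gmap = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "bp"):
        if col not in gmap.columns:
            raise ValueError(f"{map_path}: map requires column {col!r}")
    gmap = gmap.set_index("snp_id")
    absent = [s for s in snp_ids if s not in gmap.index]
    if absent:
        raise ValueError(f"SNPs absent from map: {absent[:5]}")
    chrom = gmap.loc[snp_ids, "chrom"].to_numpy(dtype=object)
    bp = gmap.loc[snp_ids, "bp"].to_numpy(dtype=np.int64)

    order = sorted(
        range(len(snp_ids)), key=lambda i: (chrom_sort_key(chrom[i]), bp[i])
    )
    return GenotypeMatrix(
        animals,
        [snp_ids[i] for i in order],
        codes[:, order],
        chrom[order],
        bp[order],
        [alleles[i] for i in order] if alleles else None,
    )


def _parse_codes(block: pd.DataFrame, path) -> np.ndarray:
    arr = block.to_numpy(dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("NA", "", "."):
                out[i, j] = MISSING
                continue
            try:
                c = int(v)
            except ValueError as exc:
                raise ValueError(f"{path}: bad genotype code {v!r}") from exc
            if c not in (0, 1, 2):
                raise ValueError(f"{path}: genotype code {c} outside {{0,1,2}}")
            out[i, j] = c
    return out


def write_genotypes(geno: GenotypeMatrix, geno_path, map_path) -> None:
    """Write the ``tsv012`` dialect plus its map TSV."""
    codes = geno.codes.astype(object)
    codes[codes == MISSING] = "NA"
    df = pd.DataFrame(codes, columns=geno.snp_ids)
    df.insert(0, "animal_id", geno.animal_ids)
    df.to_csv(geno_path, sep="\t", index=False)
    geno.map_frame().to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes (BED)
# ---------------------------------------------------------------------------

def read_gene_table(path) -> GeneTable:
    """Read a BED3+ file (chrom, start, end, name[, score, strand]).

    BED's 0-based half-open intervals become 1-based inclusive internally
    (start+1, end).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >=4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append(
                {"gene_id": name, "chrom": chrom, "start": start + 1,
                 "end": end, "strand": strand}
            )
    frame = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    return GeneTable(frame)


def write_gene_table(genes: GeneTable, path) -> None:
    with open(path, "w") as fh:
        for r in genes.frame.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured run configuration; every CLI flag overrides a config key."""

    paths: dict = field(default_factory=dict)
    ages: tuple = DEFAULT_AGES
    models: tuple = ("brody", "bertalanffy", "logistic", "gompertz", "richards")
    qc: dict = field(default_factory=lambda: {
        "ind_call": 0.95, "snp_call": 0.95, "maf": 0.01, "hwe_p": 1e-7,
    })
    scan: dict = field(default_factory=lambda: {
        "alpha": 0.05, "p_threshold": 0.001,
    })
    seed: int = 1


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "paths" in raw:
        cfg.paths = dict(raw["paths"])
    if "ages" in raw:
        cfg.ages = tuple(float(a) for a in raw["ages"])
    if "models" in raw:
        cfg.models = tuple(raw["models"])
    if "qc" in raw:
        cfg.qc.update(raw["qc"])
    if "scan" in raw:
        cfg.scan.update(raw["scan"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
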
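"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive base pairs internally; BED input is
  converted at the read boundary.
* Chromosome labels are opaque strings ("1".."29", "X", ...); sorting places
  numeric labels first in numeric order, then the rest lexicographically.
* The missing-genotype sentinel is ``MISSING = -1`` and is never conflated
  with the homozygote code 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

TRAITS = ("A", "b", "K")


def chrom_sort_key(label: str):
    """Sort key placing numeric chromosome labels first, in numeric order."""
    s = str(label)
    try:
        return (0, float(s), "")
    except ValueError:
        return (1, 0.0, s)


@dataclass
class WeightSeries:
    """One animal's weight-age records plus its fixed-effect factor levels.

    ``ages`` are strictly increasing time points (months for the cattle data,
    generator-defined unit otherwise); ``weights`` are body weights in kg.
    ``complete`` is False when the source row lacked one or more of the
    layout's expected ages — such animals are excluded downstream by default.
    """

    animal_id: str
    ages: np.ndarray
    weights: np.ndarray
    factors: dict[str, str] = field(default_factory=dict)
    complete: bool = True

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ages.shape != self.weights.shape or self.ages.ndim != 1:
            raise ValueError(
                f"{self.animal_id}: ages and weights must be 1-d and same length"
            )
        if len(self.ages) and np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"{self.animal_id}: ages must be strictly increasing")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"{self.animal_id}: weights must be finite")
        if np.any(self.weights <= 0):
            raise ValueError(f"{self.animal_id}: weights must be positive")

    def __len__(self) -> int:
        return len(self.ages)


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree: parents precede offspring.

    Unknown parents are ``None``. Founders have both parents unknown.
    """

    animal_ids: list[str]
    sires: list[str | None]
    dams: list[str | None]

    def __post_init__(self) -> None:
        if not (len(self.animal_ids) == len(self.sires) == len(self.dams)):
            raise ValueError("pedigree columns must have equal length")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            dupes = pd.Series(self.animal_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate animal ids in pedigree: {dupes[:5]}")
        seen: set[str] = set()
        for a, s, d in zip(self.animal_ids, self.sires, self.dams):
            for p in (s, d):
                if p is not None and p not in seen:
                    raise ValueError(
                        f"pedigree not sorted parents-first: parent {p!r} of "
                        f"{a!r} not seen yet"
                    )
            seen.add(a)

    def __len__(self) -> int:
        return len(self.animal_ids)

    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animal_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal_ids, "sire": self.sires, "dam": self.dams}
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage codes in {0, 1, 2, MISSING} plus a physical map.

    Code 0/2 are the two homozygotes (0 = first allele), 1 the heterozygote.
    Within a chromosome SNPs are sorted by bp (1-based).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # (n_animals, n_snps) int8
    chrom: np.ndarray  # (n_snps,) object/str
    bp: np.ndarray  # (n_snps,) int64
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        n, m = self.codes.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise ValueError("codes shape inconsistent with id lists")
        if len(self.chrom) != m or len(self.bp) != m:
            raise ValueError("map length inconsistent with snp_ids")
        if np.any(self.bp < 0):
            raise ValueError("bp positions must be non-negative")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.bp[sel]) < 0):
                raise ValueError(f"SNPs on chromosome {c} not sorted by bp")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def subset_animals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [idx[a] for a in ids]
        return GenotypeMatrix(
            list(ids), self.snp_ids, self.codes[rows], self.chrom, self.bp,
            self.alleles,
        )

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "bp": self.bp}
        )


@dataclass
class GeneTable:
    """Gene annotation with 1-based inclusive coordinates, sorted by position."""

    frame: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        if len(self.frame) and (self.frame["start"] > self.frame["end"]).any():
            raise ValueError("gene with start > end")
        self.frame = (
            self.frame.assign(_key=self.frame["chrom"].map(chrom_sort_key))
            .sort_values(["_key", "start"], kind="stable")
            .drop(columns="_key")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)
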
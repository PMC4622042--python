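"""Pedigree-based additive (numerator) relationship matrix.

The additive relationship a_ij is twice the kinship coefficient; the diagonal
is 1 + F_i with F_i the inbreeding coefficient. Built densely by Henderson's
tabular method, which is exact for arbitrary (acyclic) pedigrees and fast
enough for the tens of thousands of animals a national pedigree file holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PedigreeTable


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) float64, symmetric PSD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")

    def index_of(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def inbreeding(self) -> np.ndarray:
        """F_i = a_ii - 1."""
        return np.diag(self.values) - 1.0


def build_a_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Henderson's tabular method.

    For animal i with parents s, d (processed parents-first):
    a_ii = 1 + a_sd / 2 and a_ij = (a_js + a_jd) / 2 for j < i; unknown
    parents contribute zero. The PedigreeTable constructor guarantees the
    parents-first ordering this recursion needs.
    """
    n = len(ped)
    idx = ped.index_of()
    A = np.zeros((n, n))
    for i, (aid, s, d) in enumerate(zip(ped.animal_ids, ped.sires, ped.dams)):
        si = idx[s] if s is not None else -1
        di = idx[d] if d is not None else -1
        if si >= i or di >= i:
            raise ValueError(f"pedigree not sorted parents-first at {aid!r}")
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return RelationshipMatrix(list(ped.animal_ids), A)


def subset(rel: RelationshipMatrix, ids: list[str]) -> RelationshipMatrix:
    """Principal submatrix in the given id order (PSD is inherited)."""
    idx = rel.index_of()
    try:
        rows = [idx[a] for a in ids]
    except KeyError as exc:
        raise KeyError(f"animal {exc.args[0]!r} not in relationship matrix") from exc
    sub = rel.values[np.ix_(rows, rows)]
    return RelationshipMatrix(list(ids), sub)


def write_matrix(rel: RelationshipMatrix, path) -> None:
    """Debug dump: header of ids then one row per animal."""
    with open(path, "w") as fh:
        fh.write("\t".join(["animal_id", *rel.ids]) + "\n")
        for aid, row in zip(rel.ids, rel.values):
            fh.write(aid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
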
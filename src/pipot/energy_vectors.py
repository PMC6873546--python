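"""Per-structure pair-type energy vectors and the total-energy (TE) matrix.

A structure's total potential decomposes exactly over the 210 unordered
amino-acid pair types: element k of its energy vector is the sum of
pair-potential terms over all contacts whose two residues form pair type k,
and the vector's sum is the structure's total energy.  Stacking the vectors
of n structures gives the n x 210 TE matrix; subtracting column means yields
the centered CTE matrix on which the covariance analysis operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .potential import PotentialTable
from .structure_io import Structure, enumerate_contacts


@dataclass
class EnergyVector:
    values: np.ndarray  # (n_pairs,), RT units
    structure_id: str


@dataclass
class EnergyMatrix:
    values: np.ndarray          # (n, p)
    row_ids: list[str]
    column_labels: list[str]
    centered: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_labels)):
            raise ValueError("shape inconsistent with row/column labels")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="structure_id")

    @classmethod
    def from_tsv(cls, path, centered: bool = False) -> "EnergyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(i) for i in df.index], list(df.columns), centered)


def interaction_energy_vector(structure: Structure, table: PotentialTable) -> EnergyVector:
    """210-dimensional pair-type energy vector of one structure."""
    values = np.zeros(table.index.n_pairs)
    binning = table.binning
    for c in enumerate_contacts(structure, table.scheme):
        if not (binning.min <= c.distance < binning.max):
            continue
        k = table.index.index(c.res_i.code, c.res_j.code)
        values[k] += table.energies[k, binning.bin_of(c.distance)]
    return EnergyVector(values, structure.id)


def total_energy(v: EnergyVector) -> float:
    """Total potential of the structure: the sum of its pair-type energies."""
    return float(v.values.sum())


def build_te_matrix(structures: list[Structure], table: PotentialTable) -> EnergyMatrix:
    """Stack per-structure energy vectors into an (n x n_pairs) TE matrix."""
    if not structures:
        raise ValueError("empty structure list")
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids in TE matrix")
    rows = np.vstack([interaction_energy_vector(s, table).values for s in structures])
    return EnergyMatrix(rows, ids, table.index.labels, centered=False)


def center_columns(m: EnergyMatrix) -> EnergyMatrix:
    """Subtract column means (variable centering) -> the CTE matrix."""
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows to center (covariance undefined)")
    vals = m.values - m.values.mean(axis=0, keepdims=True)
    return EnergyMatrix(vals, list(m.row_ids), list(m.column_labels), centered=True)


def center_rows(m: EnergyMatrix) -> EnergyMatrix:
    """Subtract row means (per-sample centering). Provided as an alternative
    convention; the covariance analysis expects column centering."""
    vals = m.values - m.values.mean(axis=1, keepdims=True)
    return EnergyMatrix(vals, list(m.row_ids), list(m.column_labels), centered=False)


def subsample_rows(m: EnergyMatrix, n: int, seed: int = 0) -> EnergyMatrix:
    """Seeded random subset of rows (without replacement)."""
    if n > m.shape[0]:
        raise ValueError(f"cannot subsample {n} of {m.shape[0]} rows")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(m.shape[0], size=n, replace=False))
    return EnergyMatrix(
        m.values[pick], [m.row_ids[i] for i in pick], list(m.column_labels), m.centered
    )
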
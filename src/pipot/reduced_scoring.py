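"""Scoring with a restricted set of pair types (the principal-interaction model).

The reduced model keeps only a designated subset of the 210 pair types when
summing contact energies; because the total energy is linear in the pair-type
decomposition, the reduced energy equals the masked sum of the full energy
vector.  The PI statistic is the fraction of atomic contacts whose pair type
belongs to the mask, out of all contacts admitted by the contact scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_vectors import interaction_energy_vector
from .potential import PotentialTable
from .structure_io import Structure, enumerate_contacts


@dataclass(frozen=True)
class InteractionMask:
    selected: frozenset[str]   # pair labels, "ALA-GLY" style
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "selected", frozenset(self.selected))

    def __len__(self) -> int:
        return len(self.selected)

    def indices(self, index) -> np.ndarray:
        """Boolean mask over the index's canonical pair order."""
        out = np.zeros(index.n_pairs, dtype=bool)
        for label in self.selected:
            out[index.index_of_label(label)] = True
        return out

    @classmethod
    def full(cls, index) -> "InteractionMask":
        return cls(frozenset(index.labels), source="full")

    @classmethod
    def from_file(cls, path, source: str | None = None) -> "InteractionMask":
        labels = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    labels.append(line)
        return cls(frozenset(labels), source=source or str(path))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if self.source:
                fh.write(f"# source: {self.source}\n")
            for label in sorted(self.selected):
                fh.write(label + "\n")


def reduced_energy(s: Structure, table: PotentialTable, mask: InteractionMask) -> float:
    """Total energy summed over the masked pair types only."""
    if len(mask) == 0:
        raise ValueError("empty interaction mask")
    v = interaction_energy_vector(s, table)
    return float(v.values[mask.indices(table.index)].sum())


def pi_fraction(s: Structure, table: PotentialTable, mask: InteractionMask) -> float:
    """Share of atomic contacts whose pair type is in the mask.

    Counts contacts (atoms), not pair types and not energy; the denominator
    is every contact admitted by the table's scheme and distance range.
    """
    contacts = [
        c
        for c in enumerate_contacts(s, table.scheme)
        if table.binning.min <= c.distance < table.binning.max
    ]
    if not contacts:
        raise ValueError(f"structure {s.id} has no contacts under the scheme")
    keep = mask.indices(table.index)
    hit = sum(keep[table.index.index(c.res_i.code, c.res_j.code)] for c in contacts)
    return hit / len(contacts)
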
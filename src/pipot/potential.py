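"""Distance-dependent knowledge-based pair potentials.

The potential of mean force between two atoms at distance d is the log-ratio
of the observed contact frequency in a database of native structures to a
reference-state frequency,

    dE(d) = -RT * ln( f_obs(d) / f_ref(d) ),

tabulated per unordered residue-pair type and per distance bin.  Atom pairs
are typed by their residues' amino-acid identities, so the 210-pair-type
decomposition of a structure's total energy is exact by construction.

Two reference states are provided: "averaged" (the pair-type-independent
distance distribution, scaled to each pair type's total count) and
"power-law" (an ideal-gas-like r**alpha density per bin).  Energies are in RT
units with RT = 1 by default; every downstream quantity (rankings, Z-scores,
PCA contributions) is invariant to this global scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .pair_types import PairTypeIndex, canonical_index
from .structure_io import ContactScheme, Structure, enumerate_contacts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceBinning:
    """Uniform half-open distance bins [low, high) covering [min, max)."""

    min: float = 0.0
    max: float = 6.0
    width: float = 0.5

    def __post_init__(self):
        if not (self.max > self.min >= 0):
            raise ValueError("need max > min >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")
        n = (self.max - self.min) / self.width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("(max - min) must be a positive multiple of width")

    @property
    def n_bins(self) -> int:
        return int(round((self.max - self.min) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.min + self.width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.min + self.width * (np.arange(self.n_bins) + 0.5)

    def bin_of(self, d: float) -> int:
        if not (self.min <= d < self.max):
            raise ValueError(
                f"distance {d} outside binning range [{self.min}, {self.max})"
            )
        return min(int((d - self.min) / self.width), self.n_bins - 1)


@dataclass(frozen=True)
class ReferenceState:
    """Background distance distribution: "averaged" or "power-law" (r**alpha)."""

    name: str = "averaged"
    alpha: float | None = None

    def __post_init__(self):
        if self.name not in ("averaged", "power-law"):
            raise ValueError(f"unknown reference state {self.name!r}")
        if self.name == "power-law":
            if self.alpha is None:
                object.__setattr__(self, "alpha", 1.61)
            elif self.alpha < 0:
                raise ValueError("power-law exponent alpha must be >= 0")


@dataclass
class CountTable:
    """Pseudocounted pair-type x distance-bin contact counts."""

    counts: np.ndarray  # (n_pairs, n_bins), observed + pseudocount
    binning: DistanceBinning
    pseudocount: float
    index: PairTypeIndex = field(default_factory=canonical_index)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


def count_observations(
    structures: list[Structure],
    scheme: ContactScheme,
    binning: DistanceBinning,
    pseudocount: float = 0.01,
    index: PairTypeIndex | None = None,
) -> CountTable:
    """Histogram the contacts of a structure database by pair type and bin."""
    if not structures:
        raise ValueError("empty structure list")
    index = index or canonical_index()
    counts = np.zeros((index.n_pairs, binning.n_bins))
    for s in structures:
        contacts = enumerate_contacts(s, scheme)
        if not contacts:
            logger.info("structure %s contributed no contacts", s.id)
        for c in contacts:
            if not (binning.min <= c.distance < binning.max):
                continue
            k = index.index(c.res_i.code, c.res_j.code)
            counts[k, binning.bin_of(c.distance)] += 1.0
    counts += pseudocount
    return CountTable(counts, binning, pseudocount, index)


def reference_frequencies(counts: CountTable, ref: ReferenceState) -> np.ndarray:
    """Reference table, each pair-type row normalized to its observed row total."""
    obs = counts.counts
    grand = counts.grand_total
    if grand <= 0:
        raise ValueError("count table has zero grand total")
    if ref.name == "averaged":
        return np.outer(counts.row_totals, counts.col_totals) / grand
    # power-law: per-bin weight ~ r**alpha * width at the bin center
    w = counts.binning.centers ** ref.alpha * counts.binning.width
    w = w / w.sum()
    return np.outer(counts.row_totals, w)


@dataclass
class PotentialTable:
    """Per-pair-type, per-bin energies of a trained potential (RT units)."""

    energies: np.ndarray  # (n_pairs, n_bins)
    binning: DistanceBinning
    scheme: ContactScheme
    reference: ReferenceState
    pseudocount: float = 0.01
    rt: float = 1.0
    index: PairTypeIndex = field(default_factory=canonical_index)

    def pair_energy(self, res_a: str, res_b: str, d: float) -> float:
        """Energy of an atom pair typed (res_a, res_b) at distance d."""
        return float(self.energies[self.index.index(res_a, res_b), self.binning.bin_of(d)])

    def to_tsv(self, path) -> None:
        header = {
            "scheme": asdict(self.scheme),
            "binning": asdict(self.binning),
            "reference": asdict(self.reference),
            "pseudocount": self.pseudocount,
            "rt": self.rt,
            "alphabet": list(self.index.alphabet),
        }
        edges = self.binning.edges
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("pair_label\tbin_low\tbin_high\tenergy\n")
            for k, label in enumerate(self.index.labels):
                for b in range(self.binning.n_bins):
                    fh.write(
                        f"{label}\t{edges[b]:.17g}\t{edges[b + 1]:.17g}"
                        f"\t{self.energies[k, b]:.17g}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "PotentialTable":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing JSON header line")
            meta = json.loads(first[1:])
            fh.readline()  # column header
            index = PairTypeIndex(meta["alphabet"])
            binning = DistanceBinning(**meta["binning"])
            energies = np.zeros((index.n_pairs, binning.n_bins))
            for line in fh:
                label, low, _high, energy = line.rstrip("\n").split("\t")
                k = index.index_of_label(label)
                energies[k, binning.bin_of(float(low))] = float(energy)
        return cls(
            energies,
            binning,
            ContactScheme(**meta["scheme"]),
            ReferenceState(**meta["reference"]),
            meta["pseudocount"],
            meta["rt"],
            index,
        )


def compute_potential(
    counts: CountTable,
    ref: ReferenceState,
    scheme: ContactScheme,
    rt: float = 1.0,
) -> PotentialTable:
    """Turn a count table into energies via -RT ln(obs/ref)."""
    reference = reference_frequencies(counts, ref)
    bad = np.argwhere(reference <= 0)
    if len(bad):
        k, b = bad[0]
        raise ValueError(f"non-positive reference frequency at pair {k}, bin {b}")
    energies = -rt * np.log(counts.counts / reference)
    return PotentialTable(
        energies, counts.binning, scheme, ref, counts.pseudocount, rt, counts.index
    )


class KnowledgeBasedPotential(BaseEstimator):
    """Trainable distance-dependent knowledge-based pair potential.

    Fitting counts atom-atom contacts in a database of native structures,
    histograms them by unordered residue-pair type and distance bin, and
    converts frequencies into energies against the chosen reference state.

    Parameters
    ----------
    scheme : ContactScheme, default all-heavy atoms within 6 A
    binning : DistanceBinning, default 0.5 A bins from 0 to the scheme cutoff
    reference : ReferenceState, default "averaged"
    pseudocount : float, count added to every cell (avoids log of zero)
    rt : float, global energy scale (RT units)

    Attributes
    ----------
    counts_ : CountTable
    table_ : PotentialTable
    """

    def __init__(
        self,
        scheme: ContactScheme | None = None,
        binning: DistanceBinning | None = None,
        reference: ReferenceState | None = None,
        pseudocount: float = 0.01,
        rt: float = 1.0,
    ):
        self.scheme = scheme
        self.binning = binning
        self.reference = reference
        self.pseudocount = pseudocount
        self.rt = rt

    def _resolved(self):
        scheme = self.scheme if self.scheme is not None else ContactScheme()
        binning = (
            self.binning
            if self.binning is not None
            else DistanceBinning(0.0, scheme.cutoff, 0.5)
        )
        reference = self.reference if self.reference is not None else ReferenceState()
        return scheme, binning, reference

    def fit(self, structures: list[Structure], y=None) -> "KnowledgeBasedPotential":
        scheme, binning, reference = self._resolved()
        self.counts_ = count_observations(
            structures, scheme, binning, pseudocount=self.pseudocount
        )
        self.table_ = compute_potential(self.counts_, reference, scheme, rt=self.rt)
        return self

    def pair_energy(self, res_a: str, res_b: str, d: float) -> float:
        return self.table_.pair_energy(res_a, res_b, d)

    def energy_vector(self, structure: Structure):
        from .energy_vectors import interaction_energy_vector

        return interaction_energy_vector(structure, self.table_)

    def score_structure(self, structure: Structure, mask=None) -> float:
        """Total energy of a structure; lower is better (more native-like)."""
        if mask is None:
            return float(self.energy_vector(structure).values.sum())
        from .reduced_scoring import reduced_energy

        return reduced_energy(structure, self.table_, mask)

    def transform(self, structures: list[Structure]) -> np.ndarray:
        """Stack the structures' 210-dimensional pair-type energy vectors."""
        from .energy_vectors import build_te_matrix

        return build_te_matrix(structures, self.table_).values
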
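"""Seeded generators for synthetic natives, decoy ladders and planted matrices.

These let every stage of the pipeline run end-to-end without any external
database: compact self-avoiding chains with random 20-letter sequences play
the role of native structures; Gaussian coordinate perturbation of a native
produces a ladder of decoys spanning a range of RMSDs; and planted
high-variance Gaussian columns emulate the covariance structure the
principal-interaction selection assumes.  All generators are pure functions
of their specs (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoy_eval import DecoySet
from .energy_vectors import EnergyMatrix
from .pair_types import AMINO_ACIDS
from .structure_io import Atom, Residue, Structure, calpha_rmsd


@dataclass(frozen=True)
class ChainSpec:
    """Self-avoiding random-walk chain of single-center residues.

    bond_length is the fixed spacing of consecutive centers (3.8 A, the
    typical C-alpha virtual bond); excluded_volume_radius is the minimum
    distance allowed between non-consecutive centers; compactness in [0, 1)
    biases each step toward the current centroid so chains fold back on
    themselves and develop non-local contacts, as globular proteins do.
    """

    length: int = 30
    sequence_mode: str = "random"
    sequence: tuple[str, ...] | None = None
    bond_length: float = 3.8
    excluded_volume_radius: float = 3.0
    compactness: float = 0.3
    seed: int = 0
    max_restarts: int = 50
    max_step_tries: int = 100

    def __post_init__(self):
        if self.length < 5:
            raise ValueError("chain length must be >= 5")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.sequence_mode not in ("random", "fixed"):
            raise ValueError(f"unknown sequence_mode {self.sequence_mode!r}")
        if self.sequence_mode == "fixed" and (
            self.sequence is None or len(self.sequence) != self.length
        ):
            raise ValueError("fixed sequence_mode requires a sequence of matching length")


@dataclass(frozen=True)
class DecoyLadderSpec:
    """Per-decoy isotropic Gaussian coordinate noise magnitudes (Angstrom)."""

    noise_sds: tuple[float, ...]
    seed: int = 0

    def __post_init__(self):
        if any(sd < 0 for sd in self.noise_sds):
            raise ValueError("noise magnitudes must be >= 0")

    @property
    def n_decoys(self) -> int:
        return len(self.noise_sds)


@dataclass(frozen=True)
class PlantedMatrixSpec:
    """Independent Gaussian columns with a high-variance planted subset."""

    n_rows: int = 500
    p: int = 210
    planted_indices: tuple[int, ...] = ()
    planted_sd: float = 10.0
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (self.planted_sd > self.background_sd > 0):
            raise ValueError("need planted_sd > background_sd > 0")
        if any(not (0 <= i < self.p) for i in self.planted_indices):
            raise ValueError("planted indices out of range")


def generate_chain(spec: ChainSpec, structure_id: str | None = None) -> Structure:
    """Compact self-avoiding walk with one CA center per residue."""
    rng = np.random.default_rng(spec.seed)
    if spec.sequence_mode == "fixed":
        seq = list(spec.sequence)
    else:
        seq = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), spec.length)]
    for _ in range(spec.max_restarts):
        coords = _try_walk(spec, rng)
        if coords is not None:
            break
    else:
        raise RuntimeError(
            "chain placement failed; relax excluded_volume_radius or compactness"
        )
    sid = structure_id or f"chain-{spec.seed}"
    residues = [
        Residue(code, i, [Atom("CA", "C", coords[i])]) for i, code in enumerate(seq)
    ]
    return Structure(sid, "A", residues)


def _try_walk(spec: ChainSpec, rng: np.random.Generator) -> np.ndarray | None:
    coords = np.zeros((spec.length, 3))
    coords[1] = [spec.bond_length, 0.0, 0.0]
    for i in range(2, spec.length):
        centroid = coords[:i].mean(axis=0)
        for _ in range(spec.max_step_tries):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            if norm > 0:
                step = (1 - spec.compactness) * step + spec.compactness * pull / norm
                step /= np.linalg.norm(step)
            cand = coords[i - 1] + spec.bond_length * step
            dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            if np.all(dists >= spec.excluded_volume_radius):
                coords[i] = cand
                break
        else:
            return None
    return coords


def generate_decoy_ladder(native: Structure, spec: DecoyLadderSpec) -> DecoySet:
    """Decoys = native coordinates + isotropic Gaussian noise per atom.

    The realized C-alpha RMSD (after superposition) of each decoy is recorded
    as its provided RMSD; monotone noise magnitudes give stochastically
    increasing RMSDs.
    """
    rng = np.random.default_rng(spec.seed)
    base = native.all_coords()
    decoys = []
    for d, sd in enumerate(spec.noise_sds):
        coords = base + rng.normal(scale=sd, size=base.shape) if sd > 0 else base.copy()
        decoy = native.with_coords(coords, new_id=f"{native.id}/decoy-{d:03d}")
        decoys.append((decoy, calpha_rmsd(native, decoy)))
    return DecoySet(native.id, native, decoys)


def generate_planted_matrix(
    spec: PlantedMatrixSpec, column_labels: list[str] | None = None
) -> EnergyMatrix:
    """n x p matrix of independent Gaussian columns with planted variance."""
    rng = np.random.default_rng(spec.seed)
    sds = np.full(spec.p, spec.background_sd)
    sds[list(spec.planted_indices)] = spec.planted_sd
    values = rng.normal(size=(spec.n_rows, spec.p)) * sds
    if column_labels is None:
        if spec.p == 210:
            from .pair_types import canonical_index

            column_labels = canonical_index().labels
        else:
            column_labels = [f"var{i:03d}" for i in range(spec.p)]
    rows = [f"sample{i:04d}" for i in range(spec.n_rows)]
    return EnergyMatrix(values, rows, column_labels, centered=False)
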
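"""Canonical amino-acid alphabet and indexing of unordered pair types.

For the 20 standard amino acids there are 20*21/2 = 210 unordered pairs
(self-pairs included).  Every tabular artefact in this package orders pair
types by this module's canonical index, so the ordering must be fixed:
residue codes are sorted alphabetically by three-letter code, and pairs
(A, B) with A <= B are enumerated in lexicographic order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

# Alphabetical by three-letter code.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Nonstandard residues mapped onto a standard parent; anything else is skipped.
NONSTANDARD_MAP: dict[str, str] = {"MSE": "MET"}

N_PAIR_TYPES = len(AMINO_ACIDS) * (len(AMINO_ACIDS) + 1) // 2  # 210


class PairTypeIndex:
    """Bijection between unordered residue-code pairs and integers 0..n-1.

    Parameters
    ----------
    alphabet : sequence of str, optional
        Ordered residue codes.  Defaults to the 20 standard amino acids.
        A reduced alphabet (e.g. 3 codes -> 6 pair types) is supported so
        small exhaustive tests stay cheap.
    """

    def __init__(self, alphabet: Sequence[str] | None = None):
        codes = tuple(alphabet) if alphabet is not None else AMINO_ACIDS
        if len(set(codes)) != len(codes):
            raise ValueError("alphabet contains duplicate residue codes")
        self.alphabet: tuple[str, ...] = codes
        self.pairs: list[tuple[str, str]] = []
        self._index: dict[tuple[str, str], int] = {}
        for i, a in enumerate(codes):
            for b in codes[i:]:
                idx = len(self.pairs)
                self.pairs.append((a, b))
                self._index[(a, b)] = idx
                self._index[(b, a)] = idx

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def index(self, res_a: str, res_b: str) -> int:
        """Return the canonical index of the unordered pair (res_a, res_b)."""
        try:
            return self._index[(res_a, res_b)]
        except KeyError:
            bad = res_a if res_a not in self.alphabet else res_b
            raise ValueError(
                f"unknown residue code {bad!r}; expected one of {self.alphabet}"
            ) from None

    def label(self, idx: int) -> str:
        a, b = self.pairs[idx]
        return f"{a}-{b}"

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]

    def index_of_label(self, label: str) -> int:
        a, _, b = label.partition("-")
        return self.index(a, b)


_CANONICAL = PairTypeIndex()


def canonical_index() -> PairTypeIndex:
    """The shared 20-letter, 210-pair canonical index."""
    return _CANONICAL


def list_pair_types(alphabet: Iterable[str] | None = None) -> list[str]:
    """Ordered labels ("ALA-GLY" style) of all unordered pair types."""
    if alphabet is None:
        return _CANONICAL.labels
    return PairTypeIndex(tuple(alphabet)).labels


def pair_index(res_a: str, res_b: str) -> int:
    """Canonical index in [0, 209] of an unordered standard-residue pair."""
    return _CANONICAL.index(res_a, res_b)


def map_residue_code(code: str) -> str | None:
    """Map a residue code into the standard alphabet, or None if unmappable."""
    code = NONSTANDARD_MAP.get(code, code)
    return code if code in AMINO_ACIDS else None
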
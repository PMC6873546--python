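"""PDB parsing, contact enumeration and C-alpha RMSD.

A parsed :class:`Structure` is a single chain of residues carrying heavy-atom
coordinates.  Contacts between atoms are enumerated under a
:class:`ContactScheme` (distance cutoff, minimum sequence separation,
optional Delaunay-tessellation edge filter, and the choice of interaction
centers); each unordered atom pair appears at most once, which realises the
1/2 factor of the usual pairwise total-energy sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .pair_types import map_residue_code

logger = logging.getLogger(__name__)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    code: str          # three-letter standard code (after nonstandard mapping)
    seq_pos: int       # 0-based sequential position in the chain
    atoms: list[Atom] = field(default_factory=list)
    label: str = ""    # author-assigned PDB residue number, kept as a label only

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [r.code for r in self.residues]

    def calpha_coords(self) -> tuple[np.ndarray, list[int]]:
        """Stacked CA coordinates and the seq positions that have a CA."""
        coords, pos = [], []
        for r in self.residues:
            ca = r.get_atom("CA")
            if ca is not None:
                coords.append(ca.coords)
                pos.append(r.seq_pos)
        return np.asarray(coords, dtype=float).reshape(-1, 3), pos

    def with_coords(self, coords: np.ndarray, new_id: str | None = None) -> "Structure":
        """Copy of the structure with all atom coordinates replaced (flat order)."""
        coords = np.asarray(coords, dtype=float)
        out = Structure(new_id or self.id, self.chain_id)
        k = 0
        for res in self.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(Atom(a.name, a.element, coords[k], a.occupancy))
                k += 1
            out.residues.append(Residue(res.code, res.seq_pos, atoms, res.label))
        if k != len(coords):
            raise ValueError(f"coordinate count mismatch: {len(coords)} given, {k} needed")
        return out

    def all_coords(self) -> np.ndarray:
        return np.asarray(
            [a.coords for r in self.residues for a in r.atoms], dtype=float
        ).reshape(-1, 3)


@dataclass(frozen=True)
class ContactScheme:
    """How atom-atom contacts are defined.

    cutoff : strict upper distance bound in Angstrom (d < cutoff).
    min_seq_sep : exclusive sequence-separation threshold; a contact requires
        |seq_pos_i - seq_pos_j| > min_seq_sep.  0 admits everything but
        intra-residue pairs; 5 keeps only non-local contacts.
    use_tessellation : restrict eligible atom pairs to Delaunay edges of the
        structure's heavy-atom point set before the distance/separation filters.
    atom_mode : "all-heavy" uses every heavy atom; "single-center" uses one
        interaction center per residue (CB, falling back to CA for glycine or
        when CB is absent).
    """

    cutoff: float = 6.0
    min_seq_sep: int = 0
    use_tessellation: bool = False
    atom_mode: str = "all-heavy"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_seq_sep < 0:
            raise ValueError("min_seq_sep must be >= 0")
        if self.atom_mode not in ("all-heavy", "single-center"):
            raise ValueError(f"unknown atom_mode {self.atom_mode!r}")


def dbni_like_scheme() -> ContactScheme:
    """Tessellated non-local contacts under 6 A (|Δseq| > 5)."""
    return ContactScheme(cutoff=6.0, min_seq_sep=5, use_tessellation=True)


def dfire_like_scheme() -> ContactScheme:
    """All atom pairs under 15 A, no sequence-separation filter."""
    return ContactScheme(cutoff=15.0, min_seq_sep=0, use_tessellation=False)


@dataclass
class Contact:
    res_i: Residue
    res_j: Residue
    atom_i: Atom
    atom_j: Atom
    distance: float


_HYDROGEN = {"H", "D"}


def read_pdb(path, chain: str | None = None, structure_id: str | None = None) -> Structure:
    """Parse one chain of a PDB file into a :class:`Structure`.

    Waters and hetero compounds are dropped (MSE is mapped to MET and kept);
    for altloc duplicates the highest-occupancy conformer is retained;
    hydrogens are excluded; residues left without heavy atoms are dropped.
    Only the first MODEL of a multi-model file is read.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in PDB file {path}")
    model = st[0]
    names = [ch.name for ch in model]
    if not names:
        raise ValueError(f"no chains in PDB file {path}")
    if chain is None:
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise KeyError(f"chain {chain!r} not found; available chains: {names}")
    sid = structure_id or (st.name or str(path))
    out = Structure(sid, gchain.name)
    for gres in gchain:
        if gres.is_water():
            continue
        code = map_residue_code(gres.name)
        if code is None:
            logger.warning("skipping nonstandard residue %s %s", gres.name, gres.seqid)
            continue
        best: dict[str, Atom] = {}
        for ga in gres:
            if ga.element.name.upper() in _HYDROGEN or ga.element.is_hydrogen:
                continue
            atom = Atom(ga.name, ga.element.name,
                        np.array([ga.pos.x, ga.pos.y, ga.pos.z]), ga.occ)
            prev = best.get(ga.name)
            if prev is None or atom.occupancy > prev.occupancy:
                best[ga.name] = atom
        if not best:
            continue
        res = Residue(code, len(out.residues), list(best.values()), str(gres.seqid))
        out.residues.append(res)
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write single-chain ATOM records (enough for round-tripping fixtures)."""
    lines = []
    serial = 1
    chain = (structure.chain_id or "A")[0]
    for res in structure.residues:
        for atom in res.atoms:
            x, y, z = atom.coords
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res.code:>4s} {chain}{res.seq_pos + 1:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _interaction_atoms(structure: Structure, scheme: ContactScheme):
    """Flat lists (atom, residue) of the scheme's eligible interaction atoms."""
    out = []
    for res in structure.residues:
        if scheme.atom_mode == "single-center":
            center = res.get_atom("CB") or res.get_atom("CA")
            if center is not None:
                out.append((center, res))
        else:
            out.extend((a, res) for a in res.atoms)
    return out


def enumerate_contacts(structure: Structure, scheme: ContactScheme) -> list[Contact]:
    """All atom-atom contacts satisfying the scheme, each unordered pair once."""
    if len(structure.residues) < 2:
        logger.info("structure %s has <2 residues; no contacts", structure.id)
        return []
    entries = _interaction_atoms(structure, scheme)
    if len(entries) < 2:
        return []
    coords = np.asarray([a.coords for a, _ in entries])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(scheme.cutoff, output_type="ndarray")
    if scheme.use_tessellation and len(coords) >= 4:
        edges = _delaunay_edges(coords)
        keep = [tuple(sorted(p)) in edges for p in pairs]
        pairs = pairs[np.asarray(keep, dtype=bool)] if len(pairs) else pairs
    contacts = []
    for i, j in pairs:
        atom_i, res_i = entries[i]
        atom_j, res_j = entries[j]
        if abs(res_i.seq_pos - res_j.seq_pos) <= scheme.min_seq_sep:
            continue
        d = float(np.linalg.norm(atom_i.coords - atom_j.coords))
        if d >= scheme.cutoff:  # strict: query_pairs includes d == cutoff
            continue
        if res_j.seq_pos < res_i.seq_pos:
            res_i, res_j, atom_i, atom_j = res_j, res_i, atom_j, atom_i
        contacts.append(Contact(res_i, res_j, atom_i, atom_j, d))
    return contacts


def _delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]]:
    try:
        tess = Delaunay(coords)
    except QhullError:
        # Degenerate point sets (coplanar/collinear): joggle the input.
        tess = Delaunay(coords, qhull_options="QJ")
    edges: set[tuple[int, int]] = set()
    for simplex in tess.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((i, j) if i < j else (j, i))
    return edges


def _paired_calphas(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"residue count mismatch: {len(a.residues)} vs {len(b.residues)}"
        )
    pa, pb = [], []
    for ra, rb in zip(a.residues, b.residues):
        ca_a, ca_b = ra.get_atom("CA"), rb.get_atom("CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a.coords)
            pb.append(ca_b.coords)
    if len(pa) < 1:
        raise ValueError("no shared C-alpha pairs between structures")
    return np.asarray(pa), np.asarray(pb)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between paired point sets after optimal rigid superposition."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff ** 2).sum() / len(p)))


def calpha_rmsd(a: Structure, b: Structure, superpose: bool = True) -> float:
    """C-alpha RMSD between two conformations of the same chain.

    Residues are paired positionally; pairs where either member lacks a CA
    are excluded.  By default an optimal least-squares rigid-body fit is
    applied first; ``superpose=False`` compares coordinates as given.
    """
    pa, pb = _paired_calphas(a, b)
    if not superpose:
        return float(np.sqrt(((pa - pb) ** 2).sum() / len(pa)))
    return kabsch_rmsd(pa, pb)
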
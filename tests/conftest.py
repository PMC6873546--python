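import numpy as np
import pytest

import pipot as pp

# Hand-written two-residue PDB: ALA (3 heavy atoms incl. an altloc'd CB) and
# GLY (2 heavy atoms), plus a water and a hydrogen that must be dropped.
TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB AALA A   1       2.000   1.400   0.000  0.60  0.00           C
ATOM      4  CB BALA A   1       2.100   1.300   0.200  0.40  0.00           C
ATOM      5  HA  ALA A   1       1.500  -0.500   0.900  1.00  0.00           H
ATOM      6  N   GLY A   2       2.100  -1.200   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.500  -1.500   0.300  1.00  0.00           C
HETATM    8  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""

# Selenomethionine (MSE, a HETATM) must be parsed as MET.
MSE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C
HETATM    3 SE   MSE A   2       5.200   1.100   0.400  1.00  0.00          SE
ATOM      4  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


@pytest.fixture
def mse_pdb(tmp_path):
    p = tmp_path / "mse.pdb"
    p.write_text(MSE_PDB)
    return p


def make_point_structure(codes, coords, structure_id="toy"):
    """Structure of single-atom (CA) residues at given coordinates."""
    residues = [
        pp.Residue(code, i, [pp.Atom("CA", "C", np.asarray(xyz, float))])
        for i, (code, xyz) in enumerate(zip(codes, coords))
    ]
    return pp.Structure(structure_id, "A", residues)


@pytest.fixture(scope="session")
def natives():
    """20 compact synthetic chains of length 30 (the training database)."""
    return [
        pp.generate_chain(pp.ChainSpec(length=30, seed=s), f"nat-{s:02d}")
        for s in range(20)
    ]


@pytest.fixture(scope="session")
def trained_potential(natives):
    """Potential trained at the synthetic-study defaults."""
    scheme = pp.ContactScheme(cutoff=6.0, min_seq_sep=0, atom_mode="single-center")
    return pp.KnowledgeBasedPotential(
        scheme=scheme,
        binning=pp.DistanceBinning(0.0, 6.0, 1.0),
        reference=pp.ReferenceState("power-law", 0.0),
        pseudocount=1.0,
    ).fit(natives)
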
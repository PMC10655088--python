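import numpy as np
import pytest

from picontact.synthetic import make_peptide, make_residue

GLY_PDB = """\
ATOM      1  N   GLY A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       2.153   1.062   0.000  1.00  0.00           O
END
"""

NINE_RESIDUES = ("ARG", "HIS", "ASP", "GLU", "ASN", "GLN", "PHE", "TYR", "TRP")


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path


@pytest.fixture
def tripeptide_atoms():
    return make_peptide(["ALA", "PHE", "ALA"])


@pytest.fixture
def nine_residue_atoms():
    """One hydrogen-complete copy of each planar-side-chain residue type."""
    return make_peptide(NINE_RESIDUES)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
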
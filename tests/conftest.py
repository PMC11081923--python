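import numpy as np
import pandas as pd
import pytest

from tandemnmr import AtomRecord, ShiftTable, Structure

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.023   2.812   0.100  1.00  0.00           C
ATOM      7  C   GLY A   2       5.520   2.600   0.200  1.00  0.00           C
ATOM      8  O   GLY A   2       6.010   1.480   0.300  1.00  0.00           O
ATOM      9  N   SER A   3       6.250   3.700   0.250  1.00  0.00           N
ATOM     10  CA  SER A   3       7.700   3.650   0.350  1.00  0.00           C
ATOM     11  C   SER A   3       8.300   5.050   0.450  1.00  0.00           C
ATOM     12  O   SER A   3       7.600   6.060   0.400  1.00  0.00           O
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def gapped_pdb(tmp_path):
    lines = [l for l in THREE_RESIDUE_PDB.splitlines(keepends=True) if " A   2 " not in l]
    path = tmp_path / "gapped.pdb"
    path.write_text("".join(lines))
    return path


def make_shift_table(rows, sequence=None):
    """rows: iterable of (residue_number, residue_name, atom_name, shift)."""
    df = pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom_name", "shift"])
    return ShiftTable(entries=df, sequence=dict(sequence) if sequence else {})


def toy_structure(atoms):
    """atoms: iterable of (resnum, resname, atom_name, element, xyz)."""
    return Structure(
        atoms=[
            AtomRecord("A", num, resname, name, elem, np.asarray(xyz, dtype=float))
            for num, resname, name, elem, xyz in atoms
        ]
    )
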
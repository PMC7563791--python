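import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from actraj.model_io import Atom, Structure

# A complete two-residue peptide fragment with explicit hydrogens, two altloc
# variants on one atom and a second chain -- exercises parsing, selections and
# element inference. Columns follow the fixed PDB layout.
FIXTURE_PDB = """\
ATOM      1  N   ALA A 408      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A 408      11.639   6.072  -5.147  1.00  0.00           C
ATOM      3  C   ALA A 408      12.759   7.096  -4.941  1.00  0.00           C
ATOM      4  O   ALA A 408      13.164   7.797  -5.865  1.00  0.00           O
ATOM      5  CB  ALA A 408      10.521   6.291  -4.113  1.00  0.00           C
ATOM      6  H   ALA A 408      10.341   5.512  -6.719  1.00  0.00           H
ATOM      7  N   SER A 409      13.255   7.202  -3.708  1.00  0.00           N
ATOM      8  CA ASER A 409      14.329   8.140  -3.392  0.50  0.00           C
ATOM      9  CA BSER A 409      14.429   8.240  -3.492  0.50  0.00           C
ATOM     10  C   SER A 409      15.668   7.683  -3.962  1.00  0.00           C
ATOM     11  O   SER A 409      15.871   6.492  -4.201  1.00  0.00           O
ATOM     12  OG ASER A 409      13.992   9.447  -3.850  0.50  0.00           O
ATOM     13  OG BSER A 409      14.092   9.547  -3.950  0.50  0.00           O
ATOM     14  N   GLY B  10       2.000   1.000   0.500  1.00  0.00           N
ATOM     15  CA  GLY B  10       3.400   1.200   0.800  1.00  0.00           C
ATOM     16  C   GLY B  10       4.300   0.100   0.300  1.00  0.00           C
ATOM     17  O   GLY B  10       4.000  -1.050   0.600  1.00  0.00           O
HETATM   18 MG   MG  B 100       8.000   8.000   8.000  1.00  0.00          MG
END
"""


@pytest.fixture
def fixture_pdb_path(tmp_path: Path) -> Path:
    path = tmp_path / "fixture.pdb"
    path.write_text(FIXTURE_PDB)
    return path


def make_atom(serial, x, y, z, name="CA", element="C", resnum=None, chain="A", vdw=1.87):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name="GLY",
        residue_number=serial if resnum is None else resnum,
        chain_id=chain,
        position=(float(x), float(y), float(z)),
        vdw_radius=vdw,
    )


def point_structure(points, chain="A", vdw=1.87) -> Structure:
    """One carbon pseudo-atom per point, each its own residue."""
    return Structure(
        [make_atom(i + 1, *p, chain=chain, vdw=vdw) for i, p in enumerate(points)]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
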
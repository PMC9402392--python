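import numpy as np
import pytest

from twostate_sbm.sbm_builder import ModelParams, build_topology
from twostate_sbm.synthetic_data import ToySpec, make_two_state_toy

# three residues, full heavy-atom backbone, known coordinates in Å
MINI_PDB = """\
TITLE     MINIMAL THREE-RESIDUE CHAIN
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM      9  N   SER A   3       6.224   3.801   0.000  1.00  0.00           N
ATOM     10  CA  SER A   3       7.679   3.770   0.000  1.00  0.00           C
ATOM     11  CB  SER A   3       8.232   5.192   0.000  1.00  0.00           C
ATOM     12  OG  SER A   3       9.644   5.181   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      3  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.200   2.300   0.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def toy():
    return make_two_state_toy(ToySpec())


@pytest.fixture(scope="session")
def toy_topology(toy):
    params = ModelParams(eps_os=1.0, eps_cs=0.8, cth_range=toy.cth_range)
    return build_topology(toy.open, toy.contacts, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
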
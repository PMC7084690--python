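import numpy as np
import pytest

from dimerlens import RandomCoilTable, gen_beta_dimer


@pytest.fixture(scope="session")
def random_coil():
    return RandomCoilTable.default()


@pytest.fixture(scope="session")
def native_dimer():
    """Idealized dimer with the wild-type-like (8,10)/(10,8) pairing."""
    return gen_beta_dimer(n_residues=17, register_offset=0, hbond_positions=[8, 10])


@pytest.fixture(scope="session")
def mutant_dimer():
    """Idealized dimer with the mutant-like (10,10) pairing (offset +1)."""
    return gen_beta_dimer(n_residues=17, register_offset=1, hbond_positions=[10])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


MINIMAL_PDB = """\
CRYST1   48.300   48.300   60.400  90.00  90.00 120.00 P 31 2 1
ATOM      1  N   ALA A   1      11.104   6.134   2.000  1.00 10.00           N
ATOM      2  CA  ALA A   1      12.560   6.351   2.000  1.00 10.00           C
ATOM      3  C   ALA A   1      13.276   5.000   2.000  1.00 10.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p
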
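import numpy as np
import pytest

from bindgraph import SyntheticSpec, generate_complex, generate_dataset


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def labeled_complex(spec):
    """One synthetic chain with binding labels plus its ligand."""
    rng = np.random.default_rng(7)
    return generate_complex(spec, rng)


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled dataset with noisy one-hot features (12 chains)."""
    sp = SyntheticSpec(n_chains=12, seed=11)
    chains, features, ligands = generate_dataset(sp)
    return chains, features, ligands


#: handcrafted 3-residue PDB: ALA, GLY, SER, each with a CA record
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       1.500   2.500   4.200  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.500   2.000   3.000  1.00  0.00           C
ATOM      5  N   SER A   3       7.000   1.000   3.000  1.00  0.00           N
ATOM      6  CA  SER A   3       8.200   2.100   3.300  1.00  0.00           C
ATOM      7  OG  SER A   3       9.000   3.000   4.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return str(p)
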
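import pytest

from covbinder.fixtures import ToyComplexSpec, make_toy_complex
from covbinder.structure import AtomRecord, ResidueRecord, StructureComplex

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
TER
ATOM      6  N   GLY B   7       5.000   5.000   5.000  1.00  0.00           N
ATOM      7  CA  GLY B   7       6.458   5.000   5.000  1.00  0.00           C
ATOM      8  C   GLY B   7       7.009   6.420   5.000  1.00  0.00           C
ATOM      9  O   GLY B   7       6.251   7.390   5.000  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture(scope="session")
def toy():
    """Default toy complex with a planted lysine-targeted adduct."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_cys():
    return make_toy_complex(ToyComplexSpec(seed=1, nucleophile="CYS"))


def ca_only_complex(rng, n_receptor=5, n_ligand=12, spread=25.0):
    """A random CA-only complex for enumeration property tests."""
    residues = []
    for i in range(n_receptor):
        pos = rng.uniform(-spread, spread, 3)
        residues.append(
            ResidueRecord("A", i + 1, "ALA", [AtomRecord("CA", "C", pos)])
        )
    for j in range(n_ligand):
        pos = rng.uniform(-spread, spread, 3)
        residues.append(
            ResidueRecord("B", 100 + j, "ALA", [AtomRecord("CA", "C", pos)])
        )
    return StructureComplex(receptor_chains=["A"], ligand_chain="B", residues=residues)
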
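import numpy as np
import pytest

from hierppi.structgraph import ProteinGraph, ResidueChain


def random_chain(n: int, rng: np.random.Generator, spread: float = 12.0) -> ResidueChain:
    """Random coordinate cloud chain (not self-avoiding; for geometry tests)."""
    coords = rng.uniform(-spread, spread, size=(n, 3))
    codes = rng.choice(
        ["ALA", "GLY", "LYS", "TRP", "SER", "GLU", "VAL"], size=n
    )
    residues = [(i + 1, str(codes[i]), coords[i]) for i in range(n)]
    return ResidueChain("test", "A", residues)


def random_graph(n: int, rng: np.random.Generator, p: float = 0.4,
                 d_feat: int = 7) -> ProteinGraph:
    """Random connected-ish protein graph with random features."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    for i in range(n - 1):  # path backbone guarantees connectivity
        A[i, i + 1] = 1.0
    A = A + A.T
    X = rng.normal(size=(n, d_feat))
    labels = [(i + 1, "ALA") for i in range(n)]
    return ProteinGraph(f"G{n}", A, X, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  LYS A   3       4.000   9.000   0.000  1.00  0.00           C
ATOM      7  CA  TRP B   1       0.000   0.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb():
    return TOY_PDB
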
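"""Contact-map graph construction from PDB chains."""

import numpy as np
import pytest

from hierppi.residue_features import (
    N_FEATURES,
    STANDARD_AMINO_ACIDS,
    ResidueFeatureTable,
)
from hierppi.structgraph import (
    ChainNotFoundError,
    EmptyChainError,
    ResidueChain,
    build_contact_map,
    build_protein_graph,
    featurize_chain,
    parse_pdb_calpha,
)

from conftest import random_chain


class TestParsePDB:
    def test_echoes_ca_coordinates(self, toy_pdb):
        chain = parse_pdb_calpha(toy_pdb, "A")
        assert len(chain) == 3
        assert chain.codes == ["ALA", "GLY", "LYS"]
        np.testing.assert_allclose(chain.coords[0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(chain.coords[2], [4.0, 9.0, 0.0])

    def test_missing_chain_raises(self, toy_pdb):
        with pytest.raises(ChainNotFoundError):
            parse_pdb_calpha(toy_pdb, "Z")

    def test_chain_without_ca_raises(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\nEND\n"
        )
        with pytest.raises(EmptyChainError):
            parse_pdb_calpha(text, "A")

    def test_missing_ca_counted(self):
        # residue 2 has no CA record
        text = "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  N   GLY A   2       1.000   0.000   0.000  1.00  0.00           N",
            "ATOM      3  CA  LYS A   3       2.000   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        chain = parse_pdb_calpha(text, "A")
        assert len(chain) == 2
        assert chain.n_missing_ca == 1

    def test_altloc_keeps_a(self):
        text = "\n".join([
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C",
            "ATOM      3  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        chain = parse_pdb_calpha(text, "A")
        assert len(chain) == 2
        np.testing.assert_allclose(chain.coords[0], [0.0, 0.0, 0.0])

    def test_record_order_invariance(self, toy_pdb):
        lines = [l for l in toy_pdb.splitlines() if l.startswith("ATOM")]
        shuffled = "\n".join(lines[::-1]) + "\nEND\n"
        a = parse_pdb_calpha(toy_pdb, "A")
        b = parse_pdb_calpha(shuffled, "A")
        assert a.codes == b.codes
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_mse_hetatm_accepted(self):
        text = "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        chain = parse_pdb_calpha(text, "A")
        assert chain.codes == ["ALA", "MSE"]


class TestContactMap:
    def test_edge_within_cutoff(self):
        chain = ResidueChain("p", "A", [
            (1, "ALA", np.array([0.0, 0.0, 0.0])),
            (2, "GLY", np.array([0.0, 0.0, 9.9])),
        ])
        assert build_contact_map(chain, 10.0).matrix[0, 1] == 1.0

    def test_cutoff_boundary_inclusive(self):
        chain = ResidueChain("p", "A", [
            (1, "ALA", np.array([0.0, 0.0, 0.0])),
            (2, "GLY", np.array([0.0, 0.0, 10.0])),
        ])
        assert build_contact_map(chain, 10.0).matrix[0, 1] == 1.0

    def test_matches_bruteforce_oracle_on_random_chains(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            chain = random_chain(n, rng)
            A = build_contact_map(chain, 10.0).matrix
            coords = chain.coords
            # O(n^2) independent oracle
            oracle = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i != j and np.sqrt(((coords[i] - coords[j]) ** 2).sum()) <= 10.0:
                        oracle[i, j] = 1.0
            np.testing.assert_array_equal(A, oracle)

    def test_density_monotone_in_cutoff(self, rng):
        chain = random_chain(40, rng)
        densities = [
            build_contact_map(chain, c).matrix.sum() for c in (4, 8, 12, 16)
        ]
        assert densities == sorted(densities)

    def test_nonfinite_coordinates_rejected(self):
        chain = ResidueChain("p", "A", [
            (1, "ALA", np.array([0.0, 0.0, np.nan])),
            (2, "GLY", np.array([0.0, 0.0, 1.0])),
        ])
        with pytest.raises(ValueError, match="non-finite"):
            build_contact_map(chain)


class TestFeatures:
    def test_table_shape_and_standardization(self):
        table = ResidueFeatureTable(standardized=True)
        vals = table.values
        assert vals.shape == (20, N_FEATURES)
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(vals.std(axis=0), 1.0, atol=1e-12)
        assert len(STANDARD_AMINO_ACIDS) == 20

    def test_identical_residues_identical_rows(self):
        chain = ResidueChain("p", "A", [
            (1, "GLY", np.zeros(3)), (2, "GLY", np.ones(3)),
        ])
        X, flags = featurize_chain(chain)
        assert X.shape == (2, 7)
        np.testing.assert_array_equal(X[0], X[1])
        assert flags == []

    def test_mse_maps_to_met(self):
        table = ResidueFeatureTable()
        row_mse, ok_mse = table.row("MSE")
        row_met, ok_met = table.row("MET")
        assert ok_mse and ok_met
        np.testing.assert_array_equal(row_mse, row_met)

    def test_unknown_code_gets_mean_row_and_flag(self):
        chain = ResidueChain("p", "A", [
            (1, "XYZ", np.zeros(3)), (2, "ALA", np.ones(3)),
        ])
        X, flags = featurize_chain(chain)
        assert flags == [0]
        table = ResidueFeatureTable()
        np.testing.assert_allclose(X[0], table.values.mean(axis=0))


class TestBuildProteinGraph:
    def test_composition_consistent(self, toy_pdb):
        g = build_protein_graph(toy_pdb, "A", 10.0)
        assert g.n == 3
        assert g.A.shape == (3, 3)
        assert g.X.shape == (3, 7)
        # coords: (1,0,0), (4,0,0), (4,9,0) -> pairwise distances 3, 9, sqrt(90)
        expected = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        np.testing.assert_array_equal(g.A, expected)

    def test_deterministic(self, toy_pdb):
        g1 = build_protein_graph(toy_pdb, "A")
        g2 = build_protein_graph(toy_pdb, "A")
        np.testing.assert_array_equal(g1.A, g2.A)
        np.testing.assert_array_equal(g1.X, g2.X)

    def test_tiny_cutoff_isolates_everything(self, toy_pdb):
        g = build_protein_graph(toy_pdb, "A", cutoff_angstrom=0.1)
        assert g.A.sum() == 0

    def test_induced_subgraph(self, rng):
        from conftest import random_graph

        g = random_graph(10, rng)
        sub = g.induced_subgraph([2, 5, 7])
        assert sub.n == 3
        np.testing.assert_array_equal(sub.A, g.A[np.ix_([2, 5, 7], [2, 5, 7])])
        np.testing.assert_array_equal(sub.X, g.X[[2, 5, 7]])
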
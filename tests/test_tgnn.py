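"""Top-view encoder: GIN aggregation oracle, pair classifier, locality."""

import numpy as np
import pytest

from hierppi._autograd import Tensor, no_grad
from hierppi.network import HierPPINet
from hierppi.tgnn import GINBlock, N_TYPES, PPIDataset, PairClassifier, TGNN

from conftest import random_graph


def make_dataset(m, edges_ij, rng):
    edges = []
    for i, j in edges_ij:
        y = np.zeros(N_TYPES)
        y[rng.integers(N_TYPES)] = 1
        edges.append((i, j, y))
    return PPIDataset([f"P{k}" for k in range(m)], edges)


class TestPPIDataset:
    def test_adjacency_symmetric_zero_diagonal(self, rng):
        ds = make_dataset(5, [(0, 1), (1, 2), (3, 4)], rng)
        A = ds.adjacency()
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert A.sum() == 6

    def test_edge_subset_adjacency(self, rng):
        ds = make_dataset(5, [(0, 1), (1, 2), (3, 4)], rng)
        A = ds.adjacency([0])
        assert A.sum() == 2 and A[0, 1] == 1

    def test_rejects_self_loop_and_bad_labels(self, rng):
        with pytest.raises(ValueError):
            make_dataset(3, [(1, 1)], rng)
        with pytest.raises(ValueError):
            PPIDataset(["a", "b"], [(0, 1, np.full(N_TYPES, 0.5))])

    def test_from_dataframe_aggregates_types(self):
        import pandas as pd

        df = pd.DataFrame({
            "protein_id_1": ["a", "a", "b"],
            "protein_id_2": ["b", "b", "c"],
            "interaction_type": ["binding", "reaction", "ptmod"],
        })
        ds = PPIDataset.from_dataframe(df)
        assert ds.m == 3 and len(ds.edges) == 2
        i, j, y = ds.edges[0]
        assert y[0] == 1 and y[1] == 1 and y.sum() == 2

    def test_off_roster_query_raises(self, rng):
        ds = make_dataset(3, [(0, 1)], rng)
        with pytest.raises(KeyError, match="not in roster"):
            ds.index_of("missing")


class TestGINBlock:
    def test_aggregate_with_zero_eps_is_plain_sum(self, rng):
        """With eps=0 and identity-like MLP, node v aggregates x_v + sum of
        neighbors (checked against a hand computation pre-MLP)."""
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        X = rng.normal(size=(3, 4))
        block = GINBlock(4, 8, 8, rng)
        agg = (Tensor(A) @ Tensor(X) + (1.0 + block.eps) * Tensor(X)).data
        np.testing.assert_allclose(agg[0], X[0] + X[1] + X[2])
        np.testing.assert_allclose(agg[1], X[1] + X[0])

    def test_isolated_node_self_only(self, rng):
        A = np.zeros((3, 3))
        X = rng.normal(size=(3, 4))
        block = GINBlock(4, 8, 8, rng)
        block.eps.data = np.asarray(0.5)
        agg = (Tensor(A) @ Tensor(X) + (1.0 + block.eps) * Tensor(X)).data
        np.testing.assert_allclose(agg, 1.5 * X)

    def test_matches_dense_oracle(self, rng):
        """Full block output equals an independent dense re-implementation."""
        m = 10
        A = (rng.random((m, m)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        X = rng.normal(size=(m, 6))
        block = GINBlock(6, 8, 8, rng)
        block.bn.training = False
        out = block(A, Tensor(X)).data
        # oracle: loop over nodes
        eps = float(block.eps.data)
        W1, b1 = block.lin1.W.data, block.lin1.b.data
        W2, b2 = block.lin2.W.data, block.lin2.b.data
        gamma, beta = block.bn.gamma.data, block.bn.beta.data
        mean, var = block.bn.running_mean, block.bn.running_var
        oracle = np.zeros((m, 8))
        for v in range(m):
            agg = (1 + eps) * X[v] + X[A[v] == 1].sum(axis=0)
            h = np.maximum(agg @ W1 + b1, 0) @ W2 + b2
            h = np.maximum(h, 0)
            oracle[v] = gamma[0] * (h - mean[0]) / np.sqrt(var[0] + block.bn.eps) + beta[0]
        np.testing.assert_allclose(out, oracle, atol=1e-6)


class TestPairClassifier:
    def test_seven_logits_and_probability_range(self, rng):
        clf = PairClassifier(8, rng)
        H = Tensor(rng.normal(size=(4, 8)))
        logits = clf.logits(H, [0, 1], [2, 3]).data
        assert logits.shape == (2, N_TYPES)
        probs = 1 / (1 + np.exp(-logits))
        assert np.all((probs > 0) & (probs < 1))

    def test_symmetric_mode_is_order_invariant(self, rng):
        clf = PairClassifier(8, rng)
        H = Tensor(rng.normal(size=(4, 8)))
        ab = clf.logits(H, [0], [3], symmetric=True).data
        ba = clf.logits(H, [3], [0], symmetric=True).data
        np.testing.assert_array_equal(ab, ba)


class TestFullNetwork:
    def _setup(self, rng, m=6, n_feat=7):
        graphs = [random_graph(int(rng.integers(6, 12)), rng, d_feat=n_feat)
                  for _ in range(m)]
        net = HierPPINet(d_in=n_feat, d1=16, d2=16, d_hidden=8, seed=3)
        return graphs, net

    def test_deterministic_predictions(self, rng):
        graphs, _ = self._setup(rng)
        A = np.zeros((6, 6))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        p1 = HierPPINet(d_in=7, d1=16, d2=16, d_hidden=8, seed=3).predict_probs(
            graphs, A, [(0, 1)]
        )
        p2 = HierPPINet(d_in=7, d1=16, d2=16, d_hidden=8, seed=3).predict_probs(
            graphs, A, [(0, 1)]
        )
        np.testing.assert_array_equal(p1, p2)

    def test_three_hop_locality(self, rng):
        """Edits farther than 3 hops from both query endpoints leave the
        prediction unchanged (3 GIN blocks = 3-hop receptive field)."""
        m = 8
        graphs = [random_graph(int(rng.integers(6, 10)), rng) for _ in range(m)]
        # path 0-1-2-3-4-5-6, query (0,1); node 7 attaches beyond 3 hops
        A = np.zeros((m, m))
        for i in range(6):
            A[i, i + 1] = A[i + 1, i] = 1
        net = HierPPINet(d_in=7, d1=16, d2=16, d_hidden=8, seed=0)
        base = net.predict_probs(graphs, A, [(0, 1)])
        A_edit = A.copy()
        A_edit[5, 7] = A_edit[7, 5] = 1  # 5 hops from 0, 4 from 1
        edited = net.predict_probs(graphs, A_edit, [(0, 1)])
        np.testing.assert_array_equal(base, edited)
        # a 2-hop edit does change it
        A_near = A.copy()
        A_near[2, 7] = A_near[7, 2] = 1
        near = net.predict_probs(graphs, A_near, [(0, 1)])
        assert np.abs(near - base).max() > 0

    def test_roster_permutation_equivariance(self, rng):
        m = 6
        graphs = [random_graph(int(rng.integers(6, 10)), rng) for _ in range(m)]
        A = np.zeros((m, m))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            A[i, j] = A[j, i] = 1
        net = HierPPINet(d_in=7, d1=16, d2=16, d_hidden=8, seed=1)
        base = net.predict_probs(graphs, A, [(0, 1), (3, 5)])
        perm = rng.permutation(m)
        inv = np.argsort(perm)
        graphs_p = [graphs[i] for i in perm]
        A_p = A[np.ix_(perm, perm)]
        pairs_p = [(inv[0], inv[1]), (inv[3], inv[5])]
        permuted = net.predict_probs(graphs_p, A_p, pairs_p)
        np.testing.assert_allclose(permuted, base, atol=1e-12)

    def test_no_edges_eps0_depends_only_on_self(self, rng):
        """With an empty PPI graph each protein's top-view embedding is a
        function of its own bottom-view embedding only."""
        graphs, net = self._setup(rng, m=2)
        A = np.zeros((2, 2))
        H = net.node_embeddings(graphs, A)
        # replacing protein 1's graph must not change protein 0's embedding
        graphs2 = [graphs[0], random_graph(9, rng)]
        H2 = net.node_embeddings(graphs2, A)
        np.testing.assert_array_equal(H[0], H2[0])
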
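"""Loss closed forms, optimization sanity, checkpoint round-trips."""

import numpy as np
import pytest

from hierppi._autograd import Tensor
from hierppi.network import CheckpointError, HierPPINet
from hierppi.tgnn import N_TYPES, PPIDataset
from hierppi.trainer import (
    TrainConfig,
    TrainState,
    load_checkpoint,
    multitask_bce_loss,
    save_checkpoint,
    train,
)

from conftest import random_graph


def probs_to_logits(p):
    p = np.asarray(p, dtype=np.float64)
    return np.log(p / (1 - p))


class TestLoss:
    def test_uniform_half_is_seven_ln_two(self):
        logits = Tensor(np.zeros((1, N_TYPES)))
        y = np.array([[1, 0, 1, 0, 1, 0, 1]], dtype=float)
        loss = multitask_bce_loss(logits, y, reduction="sum")
        np.testing.assert_allclose(float(loss.data), 7 * np.log(2), atol=1e-12)

    def test_saturated_correct_is_tiny(self):
        y = np.array([[1, 0, 1, 0, 1, 0, 1]], dtype=float)
        logits = Tensor((2 * y - 1) * 30.0)
        loss = multitask_bce_loss(logits, y, reduction="sum")
        assert float(loss.data) < 1e-3

    def test_matches_scalar_loop_oracle(self, rng):
        p = rng.uniform(0.05, 0.95, size=(3, N_TYPES))
        y = (rng.random((3, N_TYPES)) < 0.5).astype(float)
        expected = 0.0
        for i in range(3):
            for k in range(N_TYPES):
                expected += -(y[i, k] * np.log(p[i, k])
                              + (1 - y[i, k]) * np.log(1 - p[i, k]))
        got = multitask_bce_loss(Tensor(probs_to_logits(p)), y, reduction="sum")
        np.testing.assert_allclose(float(got.data), expected, atol=1e-8)
        got_mean = multitask_bce_loss(Tensor(probs_to_logits(p)), y)
        np.testing.assert_allclose(float(got_mean.data), expected / 3, atol=1e-8)

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            multitask_bce_loss(Tensor(np.zeros((1, N_TYPES))),
                               np.full((1, N_TYPES), 0.3))

    def test_loss_nonnegative(self, rng):
        logits = Tensor(rng.normal(size=(5, N_TYPES)) * 3)
        y = (rng.random((5, N_TYPES)) < 0.5).astype(float)
        assert float(multitask_bce_loss(logits, y).data) >= 0


def tiny_problem(rng, m=4):
    graphs = [random_graph(int(rng.integers(5, 9)), rng) for _ in range(m)]
    edges = []
    for i, j in [(0, 1), (1, 2), (2, 3), (0, 3), (1, 3)]:
        y = np.zeros(N_TYPES)
        y[(i + j) % N_TYPES] = 1
        edges.append((i, j, y))
    ds = PPIDataset([f"P{k}" for k in range(m)], edges)
    return graphs, ds


class TestTraining:
    def test_loss_decreases(self, rng):
        graphs, ds = tiny_problem(rng)
        net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
        cfg = TrainConfig(epochs=30, seed=0, batch_size=16)
        state = train(net, graphs, ds, list(range(len(ds.edges))), cfg)
        assert state.loss_history[-1] < state.loss_history[0]

    def test_deterministic_replay(self, rng):
        graphs, ds = tiny_problem(rng)
        traces = []
        for _ in range(2):
            net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
            cfg = TrainConfig(epochs=5, seed=0, batch_size=4)
            state = train(net, graphs, ds, list(range(len(ds.edges))), cfg)
            traces.append(state.loss_history)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_nonfinite_loss_aborts(self, rng):
        graphs, ds = tiny_problem(rng)
        net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
        net.classifier.fc.W.data *= np.inf
        cfg = TrainConfig(epochs=1, seed=0)
        with pytest.raises(FloatingPointError):
            train(net, graphs, ds, list(range(len(ds.edges))), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestGradientCheck:
    def test_classifier_gradients_match_finite_differences(self, rng):
        """Analytic end-to-end loss gradients vs central differences on a
        4-protein instance (classifier weights)."""
        graphs, ds = tiny_problem(rng)
        net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
        A_t = ds.adjacency()
        idx_i = np.array([e[0] for e in ds.edges])
        idx_j = np.array([e[1] for e in ds.edges])
        Y = ds.labels()
        net.train()

        def loss_value():
            logits = net.forward_logits(graphs, A_t, idx_i, idx_j, symmetric=False)
            return multitask_bce_loss(logits, Y)

        for p in net.parameters():
            p.grad = None
        loss_value().backward()
        W = net.classifier.fc.W
        analytic = W.grad.copy()
        eps = 1e-6
        rngl = np.random.default_rng(0)
        for _ in range(12):  # spot-check random entries
            a = rngl.integers(W.data.shape[0])
            b = rngl.integers(W.data.shape[1])
            orig = W.data[a, b]
            W.data[a, b] = orig + eps
            hi = float(loss_value().data)
            W.data[a, b] = orig - eps
            lo = float(loss_value().data)
            W.data[a, b] = orig
            fd = (hi - lo) / (2 * eps)
            denom = max(abs(fd), abs(analytic[a, b]), 1e-8)
            assert abs(analytic[a, b] - fd) / denom < 1e-4


class TestCheckpoint:
    def test_roundtrip_bit_identical_predictions(self, rng, tmp_path):
        graphs, ds = tiny_problem(rng)
        net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
        cfg = TrainConfig(epochs=3, seed=0, batch_size=4)
        state = train(net, graphs, ds, [0, 1, 2], cfg)
        A_t = ds.adjacency([0, 1, 2])
        before = net.predict_probs(graphs, A_t, [(0, 1), (2, 3)])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        restored = load_checkpoint(path)
        after = restored.net.predict_probs(graphs, A_t, [(0, 1), (2, 3)])
        np.testing.assert_array_equal(before, after)
        # provenance: config + seed recorded
        assert restored.config.seed == 0
        assert restored.epoch == 3

    def test_corrupted_file_structured_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(CheckpointError):
            load_checkpoint(path)

    def test_bn_running_stats_restored(self, rng, tmp_path):
        graphs, ds = tiny_problem(rng)
        net = HierPPINet(d_in=7, d1=8, d2=8, d_hidden=8, seed=0)
        cfg = TrainConfig(epochs=2, seed=0, batch_size=4)
        state = train(net, graphs, ds, [0, 1, 2], cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        restored = load_checkpoint(path)
        for a, b in zip(net.bn_modules(), restored.net.bn_modules()):
            np.testing.assert_array_equal(a.running_mean, b.running_mean)
            np.testing.assert_array_equal(a.running_var, b.running_var)
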
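"""End-to-end training: multi-task binary cross-entropy + Adam.

The loss sums binary cross-entropy over the 7 interaction types; for batch
optimization it is averaged over pairs (sum-over-types, mean-over-pairs),
which keeps the gradient scale independent of batch size.  Evaluation-time
loss can be reported as the plain sum over the whole set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor, bce_with_logits
from ._nn import Adam
from .network import HierPPINet


@dataclass
class TrainConfig:
    lr: float = 0.001
    adam_beta1: float = 0.99
    adam_beta2: float = 0.99
    batch_size: int = 128
    epochs: int = 500
    seed: int = 0
    deterministic: bool = True
    symmetric_pairs: bool = True   # train on both orderings of each pair
    leak_free: bool = True         # message passing over training edges only
    eval_every: int = 0            # 0 = no periodic held-out evaluation

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def multitask_bce_loss(logits: Tensor, targets, reduction: str = "mean_pairs") -> Tensor:
    """Multi-task BCE over interaction types.

    ``mean_pairs``: sum over types, mean over pairs (training form);
    ``sum``: plain sum over all (pair, type) terms (evaluation form).
    """
    targets = np.asarray(targets, dtype=np.float64)
    if targets.shape != tuple(logits.shape):
        raise ValueError("logits and targets shapes disagree")
    if not np.isin(targets, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")
    elementwise = bce_with_logits(logits, targets)
    per_pair = elementwise.sum(axis=1)
    if reduction == "mean_pairs":
        return per_pair.mean()
    if reduction == "sum":
        return per_pair.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class TrainState:
    net: HierPPINet
    config: TrainConfig
    epoch: int = 0
    loss_history: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def _training_examples(dataset, edge_indices, both_orderings: bool):
    rows = []
    for e in edge_indices:
        i, j, y = dataset.edges[e]
        rows.append((i, j, y))
        if both_orderings:
            rows.append((j, i, y))
    idx_i = np.array([r[0] for r in rows], dtype=np.intp)
    idx_j = np.array([r[1] for r in rows], dtype=np.intp)
    Y = np.array([r[2] for r in rows], dtype=np.float64)
    return idx_i, idx_j, Y


def train(
    net: HierPPINet,
    graphs,
    dataset,
    train_edges,
    config: TrainConfig,
    heldout_edges=None,
    callback=None,
) -> TrainState:
    """Optimize all parameters on the training edges.

    ``graphs`` is the list of protein graphs aligned with the dataset roster.
    Message passing uses the training-edge adjacency when ``leak_free``.
    """
    rng = np.random.default_rng(config.seed)
    A_t = dataset.adjacency(train_edges if config.leak_free else None)
    idx_i, idx_j, Y = _training_examples(dataset, train_edges, config.symmetric_pairs)
    n_examples = len(idx_i)
    optimizer = Adam(
        net.parameters(), lr=config.lr,
        beta1=config.adam_beta1, beta2=config.adam_beta2,
    )
    state = TrainState(net=net, config=config)

    for epoch in range(config.epochs):
        net.train()
        perm = rng.permutation(n_examples)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_examples, config.batch_size):
            sel = perm[start: start + config.batch_size]
            logits = net.forward_logits(
                graphs, A_t, idx_i[sel], idx_j[sel], symmetric=False
            )
            loss = multitask_bce_loss(logits, Y[sel])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        state.loss_history.append(epoch_loss / n_batches)
        state.epoch = epoch + 1
        if config.eval_every and heldout_edges is not None and (
            (epoch + 1) % config.eval_every == 0
        ):
            from .evalmetrics import best_f1

            pairs = [(dataset.edges[e][0], dataset.edges[e][1]) for e in heldout_edges]
            probs = net.predict_probs(graphs, A_t, pairs)
            f1, _ = best_f1(probs, dataset.labels(heldout_edges))
            state.metrics.setdefault("heldout_best_f1", []).append((epoch + 1, f1))
        if callback is not None:
            callback(state)
    net.eval()
    return state


def save_checkpoint(state: TrainState, path):
    extra = {
        "config": asdict(state.config),
        "epoch": state.epoch,
        "loss_history": state.loss_history,
    }
    state.net.save(path, extra_meta=extra)


def load_checkpoint(path) -> TrainState:
    net, extra = HierPPINet.load(path)
    cfg = TrainConfig(**extra["config"]) if "config" in extra else TrainConfig()
    return TrainState(
        net=net,
        config=cfg,
        epoch=extra.get("epoch", 0),
        loss_history=list(extra.get("loss_history", [])),
    )
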
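"""Bottom-view encoder: two GCN blocks + self-attention-pooling readout.

Each block computes ``BN(ReLU(D^{-1/2} (A + I) D^{-1/2} H W))`` over the
residue contact graph.  Graph convolutions are per protein
(block-diagonal); batch normalization pools statistics over the nodes of
every protein in the batch jointly, as is standard when training graph
encoders on batched graphs — per-graph statistics would cancel each
protein's own channel means and erase graph-level signal.  The readout
scores nodes with a single-channel graph convolution, keeps the top
fraction, and averages them into a fixed-length protein embedding.

Training batches run block-by-block with joint BN statistics; evaluation
runs a per-protein loop with the frozen affine BN, so batched and looped
evaluation agree bit for bit.
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import Tensor, concat_rows, no_grad
from ._nn import BatchNorm1d, glorot_uniform
from .structgraph import ProteinGraph


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization of A + I (self-loops added here, once)."""
    A_hat = np.asarray(A, dtype=np.float64) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_block(A: np.ndarray, H_in: Tensor, W: Tensor, bn: BatchNorm1d | None) -> Tensor:
    """One GCN block on a binary symmetric adjacency (no self-loops in A)."""
    if A.shape[0] != H_in.shape[0]:
        raise ValueError(
            f"adjacency ({A.shape[0]} nodes) and features ({H_in.shape[0]} rows) disagree"
        )
    if H_in.shape[1] != W.shape[0]:
        raise ValueError("feature/weight dimension mismatch")
    out = (Tensor(normalized_adjacency(A)) @ H_in @ W).relu()
    return bn(out) if bn is not None else out


def sag_readout(A: np.ndarray, H: Tensor, scorer: Tensor, keep_ratio: float,
                gated: bool = False, ahat: np.ndarray | None = None) -> Tensor:
    """Self-attention graph pooling readout.

    Nodes are scored by a one-channel graph convolution of ``H``; the top
    ``ceil(keep_ratio * n)`` nodes (stable tie-break by node index) are kept
    and mean-aggregated into a single row vector.  With ``gated`` the kept
    rows are first multiplied by tanh of their attention score (the form of
    the original self-attention pooling operator), which lets the scorer
    learn which residues matter.
    """
    if not 0.0 < keep_ratio <= 1.0:
        raise ValueError("keep_ratio must lie in (0, 1]")
    n = H.shape[0]
    k = max(1, math.ceil(keep_ratio * n))
    if ahat is None:
        ahat = normalized_adjacency(A)
    score_t = Tensor(ahat) @ H @ scorer
    with no_grad():
        scores = score_t.data.ravel()
    # stable argsort on -scores keeps lower node index first on ties
    keep = np.sort(np.argsort(-scores, kind="stable")[:k])
    kept = H.take_rows(keep)
    if gated:
        kept = kept * score_t.take_rows(keep).tanh()
    return kept.mean(axis=0, keepdims=True)


class BGNN:
    """Residue-graph encoder producing one embedding row per protein."""

    def __init__(
        self,
        d_in: int = 7,
        d1: int = 128,
        d2: int = 128,
        keep_ratio: float = 0.5,
        rng: np.random.Generator | None = None,
        gated: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        self.d1, self.d2, self.keep_ratio = d1, d2, keep_ratio
        self.gated = gated
        self.W1 = Tensor(glorot_uniform(rng, d_in, d1), requires_grad=True)
        self.W2 = Tensor(glorot_uniform(rng, d1, d2), requires_grad=True)
        self.bn1 = BatchNorm1d(d1)
        self.bn2 = BatchNorm1d(d2)
        self.scorer = Tensor(glorot_uniform(rng, d2, 1), requires_grad=True)

    @staticmethod
    def _ahat(g: ProteinGraph) -> np.ndarray:
        cached = g.__dict__.get("_ahat_cache")
        if cached is None or cached.shape[0] != g.n:
            cached = normalized_adjacency(g.A)
            g.__dict__["_ahat_cache"] = cached
        return cached

    # -- evaluation path (unpadded, bit-exact per protein) --------------------
    def _encode_one(self, g: ProteinGraph) -> Tensor:
        ahat = self._ahat(g)
        H1 = self.bn1((Tensor(ahat) @ Tensor(g.X) @ self.W1).relu())
        H2 = self.bn2((Tensor(ahat) @ H1 @ self.W2).relu())
        return sag_readout(g.A, H2, self.scorer, self.keep_ratio,
                           gated=self.gated, ahat=ahat)

    # -- training path (per-graph convolutions, joint-statistics BN) ----------
    def _stage(self, graphs, Hs, W: Tensor, bn: BatchNorm1d):
        pre = [
            (Tensor(self._ahat(g)) @ H @ W).relu() for g, H in zip(graphs, Hs)
        ]
        return bn.apply_multi(pre)

    def encode_many(self, graphs) -> Tensor:
        """Embed a batch of protein graphs (one row each, order preserved)."""
        graphs = list(graphs)
        if not self.bn1.training:
            return concat_rows([self._encode_one(g) for g in graphs])
        H1 = self._stage(graphs, [Tensor(g.X) for g in graphs], self.W1, self.bn1)
        H2 = self._stage(graphs, H1, self.W2, self.bn2)
        pooled = [
            sag_readout(g.A, H, self.scorer, self.keep_ratio, gated=self.gated,
                        ahat=self._ahat(g))
            for g, H in zip(graphs, H2)
        ]
        return concat_rows(pooled)

    def encode(self, g: ProteinGraph) -> Tensor:
        """Embed one protein graph into a 1 x d2 row."""
        if not self.bn1.training:
            return self._encode_one(g)
        return self.encode_many([g])

    def parameters(self):
        return [self.W1, self.W2, self.scorer] + self.bn1.parameters() + self.bn2.parameters()

    def bn_modules(self):
        return [self.bn1, self.bn2]
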
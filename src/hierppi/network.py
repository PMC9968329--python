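"""The full two-view network: bottom encoder, top encoder, pair classifier."""

from __future__ import annotations

import json

import numpy as np

from ._autograd import Tensor, no_grad, _sigmoid
from ._nn import set_training
from .bgnn import BGNN
from .tgnn import N_TYPES, TGNN, PairClassifier

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    pass


class HierPPINet:
    """BGNN -> TGNN -> pair classifier, trained end to end."""

    def __init__(
        self,
        d_in: int = 7,
        d1: int = 128,
        d2: int = 128,
        keep_ratio: float = 0.5,
        d_hidden: int = 64,
        n_blocks: int = 3,
        n_types: int = N_TYPES,
        seed: int = 0,
    ):
        self.hparams = dict(
            d_in=d_in, d1=d1, d2=d2, keep_ratio=keep_ratio,
            d_hidden=d_hidden, n_blocks=n_blocks, n_types=n_types, seed=seed,
        )
        rng = np.random.default_rng(seed)
        self.bgnn = BGNN(d_in, d1, d2, keep_ratio, rng)
        self.tgnn = TGNN(d2, d_hidden, n_blocks, rng)
        self.classifier = PairClassifier(d_hidden, rng, n_types)

    # -- forward --------------------------------------------------------------
    def forward_logits(self, graphs, A_t: np.ndarray, pairs_i, pairs_j,
                       symmetric: bool = True) -> Tensor:
        X_t = self.bgnn.encode_many(graphs)
        H = self.tgnn(A_t, X_t)
        return self.classifier.logits(H, pairs_i, pairs_j, symmetric=symmetric)

    def predict_probs(self, graphs, A_t: np.ndarray, pairs,
                      symmetric: bool = True) -> np.ndarray:
        """Evaluation-mode pair probabilities, shape (len(pairs), n_types)."""
        self.eval()
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        with no_grad():
            logits = self.forward_logits(
                graphs, A_t, pairs[:, 0], pairs[:, 1], symmetric=symmetric
            )
        return _sigmoid(logits.data)

    def node_embeddings(self, graphs, A_t: np.ndarray) -> np.ndarray:
        """Evaluation-mode top-view node embeddings (m x d_hidden)."""
        self.eval()
        with no_grad():
            return self.tgnn(A_t, self.bgnn.encode_many(graphs)).data

    # -- bookkeeping ----------------------------------------------------------
    def parameters(self):
        return (
            self.bgnn.parameters()
            + self.tgnn.parameters()
            + self.classifier.parameters()
        )

    def bn_modules(self):
        return self.bgnn.bn_modules() + self.tgnn.bn_modules()

    def train(self):
        set_training(self.bn_modules(), True)

    def eval(self):
        set_training(self.bn_modules(), False)

    # -- checkpointing --------------------------------------------------------
    def state_arrays(self) -> dict:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.data
        for i, bn in enumerate(self.bn_modules()):
            arrays[f"bn_{i}_mean"] = bn.running_mean
            arrays[f"bn_{i}_var"] = bn.running_var
        return arrays

    def load_state_arrays(self, arrays: dict):
        params = self.parameters()
        for i, p in enumerate(params):
            data = np.asarray(arrays[f"param_{i}"], dtype=np.float64)
            if data.shape != p.data.shape:
                raise CheckpointError(
                    f"param_{i} shape {data.shape} != expected {p.data.shape}"
                )
            p.data = data.copy()
        for i, bn in enumerate(self.bn_modules()):
            bn.load_state(
                {"running_mean": arrays[f"bn_{i}_mean"],
                 "running_var": arrays[f"bn_{i}_var"]}
            )

    def save(self, path, extra_meta: dict | None = None):
        meta = {"version": CHECKPOINT_VERSION, "hparams": self.hparams}
        if extra_meta:
            meta["extra"] = extra_meta
        arrays = self.state_arrays()
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> tuple["HierPPINet", dict]:
        try:
            with np.load(path) as arc:
                arrays = {k: arc[k] for k in arc.files}
        except Exception as exc:  # corrupt / not an archive
            raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        try:
            meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        except Exception as exc:
            raise CheckpointError("checkpoint missing metadata") from exc
        if meta.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"checkpoint version {meta.get('version')} unsupported"
            )
        net = cls(**meta["hparams"])
        net.load_state_arrays(arrays)
        net.eval()
        return net, meta.get("extra", {})
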
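"""Top-view encoder: three GIN blocks over the PPI network + pair classifier.

The PPI network is a graph whose nodes are proteins (features = bottom-view
embeddings).  Each GIN block computes
``BN(ReLU(MLP((1 + eps) x_v + sum_{u in N(v)} x_u)))`` with a two-layer MLP;
a query pair is classified from the concatenation of its two node
embeddings by a fully connected layer producing 7 interaction-type logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat_cols
from ._nn import BatchNorm1d, Linear

INTERACTION_TYPES = (
    "binding", "reaction", "catalysis", "ptmod", "inhibition", "activation",
    "expression",
)
N_TYPES = len(INTERACTION_TYPES)


@dataclass
class PPIDataset:
    """Top view: protein roster + typed multi-label edge list."""

    proteins: list  # ordered roster of protein ids
    edges: list     # (i, j, y) with y a length-7 0/1 vector
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {p: i for i, p in enumerate(self.proteins)}
        if len(self._index) != len(self.proteins):
            raise ValueError("duplicate protein ids in roster")
        m = len(self.proteins)
        for i, j, y in self.edges:
            if not (0 <= i < m and 0 <= j < m) or i == j:
                raise ValueError(f"edge ({i},{j}) outside roster or self-loop")
            y = np.asarray(y)
            if y.shape != (N_TYPES,) or not np.isin(y, (0, 1)).all():
                raise ValueError("edge labels must be length-7 binary vectors")

    @property
    def m(self) -> int:
        return len(self.proteins)

    def index_of(self, protein_id) -> int:
        try:
            return self._index[protein_id]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not in roster") from None

    def labels(self, edge_indices=None) -> np.ndarray:
        idx = range(len(self.edges)) if edge_indices is None else edge_indices
        return np.array([self.edges[e][2] for e in idx], dtype=np.float64)

    def adjacency(self, edge_indices=None) -> np.ndarray:
        """Binary symmetric m x m adjacency from a subset of edges."""
        A = np.zeros((self.m, self.m), dtype=np.float64)
        idx = range(len(self.edges)) if edge_indices is None else edge_indices
        for e in idx:
            i, j, _ = self.edges[e]
            A[i, j] = A[j, i] = 1.0
        return A

    @classmethod
    def from_dataframe(cls, df, protein_order=None) -> "PPIDataset":
        """Build from a STRING-style table with columns
        (protein_id_1, protein_id_2, interaction_type); one row per
        (pair, type), types aggregated into the multi-label vector."""
        type_idx = {t: k for k, t in enumerate(INTERACTION_TYPES)}
        cols = list(df.columns[:3])
        pairs: dict = {}
        seen: list = []
        for p1, p2, t in df[cols].itertuples(index=False):
            t = str(t).strip().lower()
            if t not in type_idx:
                raise ValueError(f"unknown interaction type {t!r}")
            key = (p1, p2) if p1 <= p2 else (p2, p1)
            if key not in pairs:
                pairs[key] = np.zeros(N_TYPES)
                seen.append(key)
            pairs[key][type_idx[t]] = 1.0
        if protein_order is None:
            protein_order = sorted({p for key in pairs for p in key})
        roster = list(protein_order)
        index = {p: i for i, p in enumerate(roster)}
        edges = [(index[a], index[b], pairs[(a, b)]) for a, b in seen]
        return cls(roster, edges)


class GINBlock:
    """One GIN block: sum aggregation with learnable epsilon + 2-layer MLP."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.lin1 = Linear(d_in, d_hidden, rng)
        self.lin2 = Linear(d_hidden, d_out, rng)
        self.eps = Tensor(np.zeros(()), requires_grad=True)
        self.bn = BatchNorm1d(d_out)

    def __call__(self, A: np.ndarray, X: Tensor) -> Tensor:
        if A.shape[0] != X.shape[0]:
            raise ValueError("adjacency and feature row counts disagree")
        agg = Tensor(np.asarray(A, dtype=np.float64)) @ X + (1.0 + self.eps) * X
        h = self.lin2(self.lin1(agg).relu())
        return self.bn(h.relu())

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters() + [self.eps] + self.bn.parameters()


class PairClassifier:
    """FC layer mapping the concatenated pair embedding to 7 type logits."""

    def __init__(self, d_node: int, rng: np.random.Generator, n_types: int = N_TYPES):
        self.fc = Linear(2 * d_node, n_types, rng)

    def logits(self, H: Tensor, pairs_i, pairs_j, symmetric: bool = True) -> Tensor:
        hi, hj = H.take_rows(pairs_i), H.take_rows(pairs_j)
        out = self.fc(concat_cols(hi, hj))
        if symmetric:
            out = (out + self.fc(concat_cols(hj, hi))) * 0.5
        return out

    def parameters(self):
        return self.fc.parameters()


class TGNN:
    """Three stacked GIN blocks over the PPI adjacency."""

    def __init__(self, d_in: int = 128, d_hidden: int = 64,
                 n_blocks: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.blocks = []
        d = d_in
        for _ in range(n_blocks):
            self.blocks.append(GINBlock(d, d_hidden, d_hidden, rng))
            d = d_hidden
        self.d_out = d

    def __call__(self, A: np.ndarray, X: Tensor) -> Tensor:
        H = X
        for block in self.blocks:
            H = block(A, H)
        return H

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()]

    def bn_modules(self):
        return [b.bn for b in self.blocks]
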
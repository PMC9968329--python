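"""Model/Results interface tying the two views together.

:class:`HierPPI` is constructed from protein graphs plus a typed interaction
table; ``fit()`` trains the two-view network end to end and returns a
:class:`HierPPIResults` carrying the fitted parameters, the loss trace,
held-out metrics, a text ``summary()``, and ``predict`` / ``explain``
methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasplit, evalmetrics, explain as explain_mod, trainer
from .network import HierPPINet
from .structgraph import ProteinGraph
from .tgnn import INTERACTION_TYPES, PPIDataset


class HierPPI:
    """Two-view hierarchical PPI model.

    Parameters
    ----------
    graphs : mapping or sequence of ProteinGraph
        Bottom-view graphs; a mapping is keyed by protein id, a sequence
        must align with the dataset roster.
    dataset : PPIDataset
        Protein roster + typed multi-label edges (the top view).
    """

    def __init__(self, graphs, dataset: PPIDataset, **net_kwargs):
        if isinstance(graphs, dict):
            missing = [p for p in dataset.proteins if p not in graphs]
            if missing:
                raise ValueError(f"graphs missing for proteins: {missing[:5]}")
            graphs = [graphs[p] for p in dataset.proteins]
        graphs = list(graphs)
        if len(graphs) != dataset.m:
            raise ValueError("one ProteinGraph per roster protein required")
        d_in = graphs[0].X.shape[1]
        self.graphs = graphs
        self.dataset = dataset
        self.net_kwargs = dict(d_in=d_in, **net_kwargs)

    @classmethod
    def from_dataframe(cls, edges_df: pd.DataFrame, graphs: dict, **net_kwargs):
        """Build from a STRING-style (protein1, protein2, type) table."""
        dataset = PPIDataset.from_dataframe(edges_df)
        return cls(graphs, dataset, **net_kwargs)

    def fit(
        self,
        split: datasplit.SplitSpec | None = None,
        config: trainer.TrainConfig | None = None,
        restarts: int = 1,
        val_fraction: float = 0.0,
    ) -> "HierPPIResults":
        """Train end to end; defaults to a random 8:2 split.

        With ``restarts > 1`` the model is trained from several
        deterministic initializations and the restart with the best
        micro-best-F1 on a validation subset carved out of the *training*
        edges is kept (the test edges are never consulted).  Standard model
        selection for small training sets, where individual runs vary.
        """
        config = config or trainer.TrainConfig()
        if split is None:
            split = datasplit.split_random(
                self.dataset.edges, test_fraction=0.2, seed=config.seed
            )
        train_edges = list(split.train_edges)
        val_edges: list = []
        if restarts > 1:
            if not 0.0 < val_fraction < 1.0:
                val_fraction = 0.2
            rng = np.random.default_rng(config.seed + 9173)
            n_val = max(1, int(round(val_fraction * len(train_edges))))
            val_edges = sorted(
                int(e) for e in rng.choice(train_edges, n_val, replace=False)
            )
            train_edges = [e for e in train_edges if e not in set(val_edges)]
        best_state, best_score = None, -np.inf
        for r in range(restarts):
            cfg_r = trainer.TrainConfig(
                **{**config.__dict__, "seed": config.seed + 101 * r}
            )
            net = HierPPINet(seed=cfg_r.seed, **self.net_kwargs)
            state = trainer.train(
                net, self.graphs, self.dataset, train_edges, cfg_r,
                heldout_edges=split.test_edges,
            )
            if restarts == 1:
                best_state = state
                break
            A_val = self.dataset.adjacency(train_edges)
            pairs = [(self.dataset.edges[e][0], self.dataset.edges[e][1])
                     for e in val_edges]
            probs = net.predict_probs(self.graphs, A_val, pairs)
            score, _ = evalmetrics.best_f1(probs, self.dataset.labels(val_edges))
            if score > best_score:
                best_state, best_score = state, score
        fit_split = datasplit.SplitSpec(
            strategy=split.strategy, test_fraction=split.test_fraction,
            seed=split.seed, train_edges=train_edges,
            test_edges=list(split.test_edges),
            known_protein_fraction=split.known_protein_fraction,
            realized_known_fraction=split.realized_known_fraction,
            realized_test_fraction=split.realized_test_fraction,
            class_shares=split.class_shares,
        )
        results = HierPPIResults(self, best_state, fit_split)
        results.val_edges = val_edges
        results.val_best_f1 = None if restarts == 1 else best_score
        return results


class HierPPIResults:
    """Fitted two-view model: parameters, diagnostics, prediction, explanation."""

    def __init__(self, model: HierPPI, state: trainer.TrainState,
                 split: datasplit.SplitSpec):
        self.model = model
        self.state = state
        self.split = split
        self.config = state.config
        # message-passing adjacency used at inference (leak-free by default)
        self.A_msg = model.dataset.adjacency(
            split.train_edges if state.config.leak_free else None
        )
        self.val_edges: list = []
        self.val_best_f1 = None
        self._report = None

    @property
    def net(self) -> HierPPINet:
        return self.state.net

    @property
    def loss_history(self):
        return self.state.loss_history

    # -- prediction -----------------------------------------------------------
    def predict(self, pairs=None) -> pd.DataFrame:
        """Type probabilities for protein pairs (default: the test edges).

        ``pairs`` may contain protein ids or roster indices.
        """
        ds = self.model.dataset
        if pairs is None:
            idx = [(ds.edges[e][0], ds.edges[e][1]) for e in self.split.test_edges]
        else:
            idx = [
                (
                    i if isinstance(i, (int, np.integer)) else ds.index_of(i),
                    j if isinstance(j, (int, np.integer)) else ds.index_of(j),
                )
                for i, j in pairs
            ]
        probs = self.net.predict_probs(self.model.graphs, self.A_msg, idx)
        out = pd.DataFrame(probs, columns=list(INTERACTION_TYPES))
        out.insert(0, "protein_1", [ds.proteins[i] for i, _ in idx])
        out.insert(1, "protein_2", [ds.proteins[j] for _, j in idx])
        return out

    def evaluate(self, edge_indices=None, threshold: float = 0.5):
        """Metric report on a set of labelled edges (default: test edges)."""
        ds = self.model.dataset
        edges = self.split.test_edges if edge_indices is None else edge_indices
        pairs = [(ds.edges[e][0], ds.edges[e][1]) for e in edges]
        probs = self.net.predict_probs(self.model.graphs, self.A_msg, pairs)
        return evalmetrics.evaluate(probs, ds.labels(edges), threshold)

    # -- explanation ----------------------------------------------------------
    def explain(self, protein, partner=None, **kwargs) -> explain_mod.ImportanceProfile:
        """Residue-importance profile of ``protein``.

        With a ``partner``, the single-query profile of
        :func:`hierppi.explain.explain_pair`; with ``partner=None``, the
        partner-averaged protein-level profile over every interaction
        partner in the message-passing graph
        (:func:`hierppi.explain.explain_protein`).
        """
        ds = self.model.dataset
        qi = protein if isinstance(protein, (int, np.integer)) else ds.index_of(protein)
        if partner is not None:
            qj = partner if isinstance(partner, (int, np.integer)) else ds.index_of(partner)
            return explain_mod.explain_pair(
                self.net, self.model.graphs, self.A_msg, qi, qj, **kwargs
            )
        nbrs = np.flatnonzero(self.A_msg[qi])
        if nbrs.size == 0:
            raise ValueError(f"protein {protein!r} has no interaction partners")
        return explain_mod.explain_protein(
            self.net, self.model.graphs, self.A_msg, qi, nbrs, **kwargs
        )

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        ds = self.model.dataset
        if self._report is None and self.split.test_edges:
            self._report = self.evaluate()
        lines = [
            "        Hierarchical two-view PPI model",
            "=" * 52,
            f"proteins:             {ds.m}",
            f"interactions:         {len(ds.edges)}",
            f"split:                {self.split.strategy} "
            f"(test fraction {self.split.test_fraction})",
            f"train / test edges:   {len(self.split.train_edges)} / "
            f"{len(self.split.test_edges)}",
            f"epochs trained:       {self.state.epoch}",
            f"final training loss:  {self.loss_history[-1]:.4f}"
            if self.loss_history else "final training loss:  n/a",
        ]
        if self.split.class_shares is not None:
            c1, c2, c3 = self.split.class_shares
            lines.append(
                f"test classes C1/C2/C3: {c1:.1f}% / {c2:.1f}% / {c3:.1f}%"
            )
        if self._report is not None:
            r = self._report
            lines += [
                "-" * 52,
                f"held-out micro-F1 @0.5:  {r.micro_f1_at_threshold:.4f}",
                f"held-out best-F1:        {r.best_f1:.4f} "
                f"(threshold {r.best_threshold:.3f})",
            ]
            for name, a in zip(INTERACTION_TYPES, r.aupr_per_type):
                lines.append(
                    f"AUPR {name:<12} {'n/a' if a is None else format(a, '.4f')}"
                )
        lines.append("=" * 52)
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path):
        trainer.save_checkpoint(self.state, path)

    def load_params(self, path):
        """Restore parameters from a checkpoint into this results object."""
        state = trainer.load_checkpoint(path)
        self.state.net.load_state_arrays(state.net.state_arrays())
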
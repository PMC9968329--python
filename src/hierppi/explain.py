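"""Residue importance for a query interaction, without residue labels.

A random connected subgraph G_s of the query protein's contact graph is
scored by the mutual information MI_s = H(Y) - H(Y | G = G_s), where Y is
the model's Bernoulli prediction for one interaction type and the
conditional prediction replaces the protein by the node-induced subgraph.
Every member of G_s receives the equal share MI_s / |G_s|; a residue's raw
importance is the mean of its shares over the samples containing it, and
z-scoring gives the reported standardized profile.

Because one forward pass yields all seven type probabilities, a single set
of subgraph samples scores every type at once.  Two selection policies are
offered for which type to explain: the highest-probability type (default),
or the type whose prediction is most *sensitive* to the query protein's
subgraphs (largest MI spread) — with multi-label redundancy a pair's
top-probability type can be one the query protein does not influence at
all, in which case its importance landscape is pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, no_grad, _sigmoid
from .structgraph import ProteinGraph

_CLIP = 1e-12


def bernoulli_entropy(p) -> np.ndarray | float:
    """Entropy of Bernoulli(p) in nats, with probability clipping."""
    p = np.clip(np.asarray(p, dtype=np.float64), _CLIP, 1.0 - _CLIP)
    out = -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
    return float(out) if out.ndim == 0 else out


def sample_subgraphs(
    g: ProteinGraph,
    n_samples: int = 200,
    size_range: tuple | None = None,
    seed: int = 0,
) -> list:
    """Connected node-induced subgraphs grown by random traversal.

    Each sample starts from a uniform root and grows through a random
    frontier until a uniform target size in ``size_range`` (default
    ``[max(2, ceil(0.1 n)), ceil(0.5 n)]``).
    """
    n = g.n
    if size_range is None:
        size_range = (max(2, int(np.ceil(0.1 * n))), int(np.ceil(0.5 * n)))
    lo, hi = size_range
    if not (2 <= lo <= hi <= n):
        raise ValueError(f"size_range {size_range} outside [2, {n}]")
    if n >= 2 and g.A.sum() == 0:
        raise ValueError("cannot sample connected subgraphs of an edgeless graph")
    rng = np.random.default_rng(seed)
    neighbors = [np.flatnonzero(g.A[v]) for v in range(n)]
    samples = []
    for _ in range(n_samples):
        target = int(rng.integers(lo, hi + 1))
        root = int(rng.integers(n))
        members = {root}
        frontier = set(neighbors[root])
        while len(members) < target and frontier:
            v = int(rng.choice(sorted(frontier)))
            members.add(v)
            frontier.discard(v)
            frontier.update(u for u in neighbors[v] if u not in members)
        if len(members) >= 2:
            samples.append(np.array(sorted(members), dtype=np.intp))
    return samples


def subgraph_mi(p_full: float, p_sub: float) -> float:
    """MI_s = H(Y) - H(Y | G = G_s) for Bernoulli predictions (nats)."""
    return bernoulli_entropy(p_full) - bernoulli_entropy(p_sub)


def node_importance(samples, mi_values, n: int, equal_share: bool = True) -> np.ndarray:
    """Raw per-residue importance z_f.

    Each sample assigns ``MI_s / |G_s|`` (or the full ``MI_s`` when
    ``equal_share`` is off) to its member nodes; a node's raw importance is
    the mean over samples containing it.  Uncovered nodes are NaN.
    """
    if len(samples) != len(mi_values):
        raise ValueError("samples and MI values disagree in length")
    total = np.zeros(n)
    count = np.zeros(n)
    for nodes, mi in zip(samples, mi_values):
        share = mi / len(nodes) if equal_share else mi
        total[nodes] += share
        count[nodes] += 1
    z_f = np.full(n, np.nan)
    covered = count > 0
    z_f[covered] = total[covered] / count[covered]
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} residues never sampled; importance undefined"
        )
    return z_f


@dataclass
class ImportanceProfile:
    protein_id: str
    partner_id: str
    type_index: int          # -1 for a multi-type aggregated profile
    z_f: np.ndarray          # raw importance (NaN where uncovered)
    mu: float
    sigma: float
    z_s: np.ndarray          # standardized importance
    n_samples: int
    degenerate: bool = False  # sigma was 0

    def predicted_site(self, use_standardized: bool = True) -> set:
        """Residues predicted as functional-surface members (importance > 0)."""
        v = self.z_s if use_standardized else self.z_f
        return set(map(int, np.flatnonzero(v > 0)))


def standardize(
    z_f: np.ndarray,
    protein_id: str = "",
    partner_id: str = "",
    type_index: int = 0,
    n_samples: int = 0,
) -> ImportanceProfile:
    """Z-score the raw importance vector (population sd over covered residues)."""
    z_f = np.asarray(z_f, dtype=np.float64)
    covered = ~np.isnan(z_f)
    vals = z_f[covered]
    mu = float(vals.mean()) if vals.size else 0.0
    sigma = float(vals.std()) if vals.size else 0.0
    z_s = np.full_like(z_f, np.nan)
    if sigma > 0:
        z_s[covered] = (vals - mu) / sigma
        degenerate = False
    else:
        z_s[covered] = 0.0
        degenerate = True
    return ImportanceProfile(
        protein_id, partner_id, type_index, z_f, mu, sigma, z_s,
        n_samples, degenerate,
    )


def make_pair_predictor(net, graphs, A_t: np.ndarray, qi: int, qj: int):
    """Closure predicting type probabilities for the pair (qi, qj) with the
    query protein optionally replaced by a subgraph; caches the other
    proteins' embeddings."""
    net.eval()
    with no_grad():
        X_base = net.bgnn.encode_many(graphs).data

    def predict(graph_override: ProteinGraph | None = None) -> np.ndarray:
        X = X_base.copy()
        if graph_override is not None:
            with no_grad():
                X[qi] = net.bgnn.encode(graph_override).data[0]
        with no_grad():
            H = net.tgnn(A_t, Tensor(X))
            logits = net.classifier.logits(
                H, np.array([qi]), np.array([qj]), symmetric=True
            )
        return _sigmoid(logits.data)[0]

    return predict


def _mi_samples(net, graphs, A_t, qi, qj, n_samples, size_range, seed):
    """Subgraph samples and their MI values for all types at once.

    Returns ``(samples, MI, p_full)`` with MI of shape (n_samples, n_types).
    """
    g = graphs[qi]
    predict = make_pair_predictor(net, graphs, A_t, qi, qj)
    p_full = predict()
    samples = sample_subgraphs(g, n_samples, size_range, seed)
    P_sub = np.array([predict(g.induced_subgraph(s)) for s in samples])
    MI = bernoulli_entropy(p_full)[None, :] - bernoulli_entropy(P_sub)
    return samples, MI, p_full


def explain_pair(
    net,
    graphs,
    A_t: np.ndarray,
    qi: int,
    qj: int,
    type_index: int | str | None = None,
    n_samples: int = 200,
    size_range: tuple | None = None,
    seed: int = 0,
    equal_share: bool = True,
) -> ImportanceProfile:
    """Importance profile of protein ``qi`` for its interaction with ``qj``.

    ``type_index`` selects the explained interaction type: an integer, the
    default ``None`` (highest predicted probability), or ``"sensitive"``
    (largest MI spread over the subgraph samples).
    """
    g = graphs[qi]
    samples, MI, p_full = _mi_samples(
        net, graphs, A_t, qi, qj, n_samples, size_range, seed
    )
    if type_index == "sensitive":
        k = int(np.argmax(MI.std(axis=0)))
    elif type_index is None:
        k = int(np.argmax(p_full))
    else:
        k = int(type_index)
    z_f = node_importance(samples, MI[:, k], g.n, equal_share)
    return standardize(
        z_f, protein_id=g.protein_id,
        partner_id=graphs[qj].protein_id, type_index=k,
        n_samples=len(samples),
    )


def explain_protein(
    net,
    graphs,
    A_t: np.ndarray,
    qi: int,
    partners,
    n_samples: int = 200,
    size_range: tuple | None = None,
    seed: int = 0,
    equal_share: bool = True,
) -> ImportanceProfile:
    """Partner-averaged residue importance for one protein.

    Each subgraph sample is scored with its *total* mutual information
    summed over the seven types — the information the subgraph carries
    about the joint presence prediction; types the protein does not
    influence contribute nothing.  Per-partner standardized profiles are
    averaged and re-standardized.  This is the recommended protein-level
    summary when several interactions are known.
    """
    partners = list(partners)
    if not partners:
        raise ValueError("need at least one partner")
    g = graphs[qi]
    acc = np.zeros(g.n)
    for r, qj in enumerate(partners):
        samples, MI, _ = _mi_samples(
            net, graphs, A_t, qi, qj, n_samples, size_range,
            seed + 7919 * r,
        )
        prof_r = standardize(
            node_importance(samples, MI.sum(axis=1), g.n, equal_share)
        )
        acc += np.nan_to_num(prof_r.z_s, nan=0.0)
    prof = standardize(
        acc / len(partners), protein_id=g.protein_id,
        partner_id="|".join(graphs[int(p)].protein_id for p in partners),
        n_samples=n_samples * len(partners),
    )
    prof.type_index = -1
    return prof


def influence_scores(
    net,
    graphs,
    A_t: np.ndarray,
    queries,
    n_substitutes: int = 15,
    seed: int = 0,
) -> dict:
    """How much each query protein's structure influences its predictions.

    For each ``(qi, qj)`` query the protein's graph is replaced by other
    proteins' graphs and the spread (summed standard deviation over types)
    of the resulting predictions is returned, keyed by ``qi``.  Uses model
    predictions only — no ground truth — so it can rank proteins by how
    explainable their interactions are: a protein whose substitution leaves
    every prediction unchanged has no residue-level story to extract.
    """
    rng = np.random.default_rng(seed)
    m = len(graphs)
    out = {}
    for qi, qj in queries:
        predict = make_pair_predictor(net, graphs, A_t, qi, qj)
        others = [p for p in range(m) if p != qi]
        subs = rng.choice(others, size=min(n_substitutes, len(others)),
                          replace=False)
        P = np.array([predict(graphs[int(s)]) for s in subs])
        out[qi] = float(P.std(axis=0).sum())
    return out
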
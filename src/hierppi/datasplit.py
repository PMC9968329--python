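"""Train/test edge partitions: random, BFS/DFS out-of-distribution splits,
network perturbation, and the C1/C2/C3 test-pair stratification.

The OOD splits grow a set of "unknown" test proteins by graph traversal from
a random root; every edge incident to that set becomes a test edge.  Growth
continues until the requested test-edge fraction is reached, then (if the
realized known-protein fraction is still too high) until that fraction drops
into the requested band; roots are re-drawn a bounded number of times.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SplitSpec:
    strategy: str
    test_fraction: float
    seed: int
    train_edges: list
    test_edges: list
    known_protein_fraction: float | None = None
    realized_known_fraction: float | None = None
    realized_test_fraction: float | None = None
    class_shares: tuple | None = None  # (C1, C2, C3) percentages

    def __post_init__(self):
        overlap = set(self.train_edges) & set(self.test_edges)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]} ...")


def _edge_endpoints(edges):
    return [(e[0], e[1]) for e in edges]


def split_random(edges, test_fraction: float = 0.2, seed: int = 0) -> SplitSpec:
    """Uniform edge split; test size is round-half-even of fraction * |E|."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(edges)
    if n < 2:
        raise ValueError("need at least 2 edges to split")
    rng = np.random.default_rng(seed)
    n_test = int(np.round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    test = rng.choice(n, size=n_test, replace=False)
    test_set = set(int(e) for e in test)
    train = [e for e in range(n) if e not in test_set]
    spec = SplitSpec(
        strategy="random", test_fraction=test_fraction, seed=seed,
        train_edges=train, test_edges=sorted(test_set),
        realized_test_fraction=n_test / n,
    )
    spec.class_shares = classify_test_pairs(spec, edges)
    return spec


def _known_fraction(edges, test_edge_set):
    """Fraction of test-incident proteins that also occur in a training edge."""
    endpoints = _edge_endpoints(edges)
    test_prots = {p for e in test_edge_set for p in endpoints[e]}
    train_prots = {
        p for e in range(len(edges)) if e not in test_edge_set for p in endpoints[e]
    }
    if not test_prots:
        return 0.0
    return len(test_prots & train_prots) / len(test_prots)


def split_ood(
    edges,
    strategy: str,
    test_fraction: float = 0.2,
    known_protein_fraction: float | None = None,
    seed: int = 0,
    tolerance: float = 0.05,
    max_retries: int = 200,
) -> SplitSpec:
    """BFS/DFS traversal split producing test edges around unseen proteins."""
    if strategy not in ("bfs", "dfs"):
        raise ValueError("strategy must be 'bfs' or 'dfs'")
    n = len(edges)
    if n < 2:
        raise ValueError("need at least 2 edges to split")
    endpoints = _edge_endpoints(edges)
    proteins = sorted({p for ij in endpoints for p in ij})
    neighbors = {p: set() for p in proteins}
    incident = {p: [] for p in proteins}
    for e, (i, j) in enumerate(endpoints):
        neighbors[i].add(j)
        neighbors[j].add(i)
        incident[i].append(e)
        incident[j].append(e)
    target_edges = max(1, int(np.round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max_retries):
        selected: set = set()
        visited: set = set()
        frontier: deque = deque()
        test_set: set = set()

        def traverse_add(p):
            selected.add(p)
            test_set.update(incident[p])
            nbrs = sorted(neighbors[p] - visited)
            rng.shuffle(nbrs)
            for q in nbrs:
                visited.add(q)
                frontier.append(q)

        def grow_one() -> bool:
            while True:
                if not frontier:
                    remaining = [p for p in proteins if p not in visited]
                    if not remaining:
                        return False
                    root = remaining[rng.integers(len(remaining))]
                    visited.add(root)
                    frontier.append(root)
                p = frontier.popleft() if strategy == "bfs" else frontier.pop()
                if p in selected:
                    continue
                traverse_add(p)
                return True

        while len(test_set) < target_edges and len(test_set) < n - 1:
            if not grow_one():
                break
        realized = _known_fraction(edges, test_set)
        if known_protein_fraction is not None:
            # too many known proteins: keep growing the unknown set
            while (
                realized > known_protein_fraction + tolerance
                and len(test_set) < n - 1
            ):
                if not grow_one():
                    break
                realized = _known_fraction(edges, test_set)
        ok = known_protein_fraction is None or (
            abs(realized - known_protein_fraction) <= tolerance
        )
        candidate = (test_set, realized)
        if best is None or (
            known_protein_fraction is not None
            and abs(realized - known_protein_fraction)
            < abs(best[1] - (known_protein_fraction or 0.0))
        ):
            best = candidate
        if ok and len(test_set) < n:
            test_sorted = sorted(test_set)
            spec = SplitSpec(
                strategy=strategy, test_fraction=test_fraction, seed=seed,
                train_edges=[e for e in range(n) if e not in test_set],
                test_edges=test_sorted,
                known_protein_fraction=known_protein_fraction,
                realized_known_fraction=realized,
                realized_test_fraction=len(test_set) / n,
            )
            spec.class_shares = classify_test_pairs(spec, edges)
            return spec
    raise RuntimeError(
        f"could not realize known-protein fraction {known_protein_fraction} "
        f"+/- {tolerance} after {max_retries} roots "
        f"(closest realized: {best[1]:.3f} with {len(best[0])} test edges)"
    )


def classify_test_pairs(split: SplitSpec, edges) -> tuple:
    """C1/C2/C3 percentage shares of the test pairs.

    C1: both endpoints occur in >= 1 training edge; C2: exactly one;
    C3: neither.
    """
    endpoints = _edge_endpoints(edges)
    train_prots = {p for e in split.train_edges for p in endpoints[e]}
    counts = [0, 0, 0]
    for e in split.test_edges:
        i, j = endpoints[e]
        k = (i in train_prots) + (j in train_prots)
        counts[2 - k] += 1
    total = max(sum(counts), 1)
    return tuple(100.0 * c / total for c in counts)


@dataclass
class PerturbedNetwork:
    edges: list                      # perturbed edge list (i, j, y)
    is_injected: np.ndarray          # True for injected false-positive edges
    removed_edges: list              # original (i, j, y) removed (false negatives)


def perturb_network(
    edges,
    n_proteins: int,
    add_ratio: float = 0.0,
    remove_ratio: float = 0.0,
    seed: int = 0,
    n_types: int = 7,
) -> PerturbedNetwork:
    """Randomly remove true edges and inject non-edges with random labels."""
    if add_ratio < 0 or remove_ratio < 0 or remove_ratio >= 1:
        raise ValueError("require add_ratio >= 0 and 0 <= remove_ratio < 1")
    rng = np.random.default_rng(seed)
    n = len(edges)
    n_remove = int(np.round(remove_ratio * n))
    n_add = int(np.round(add_ratio * n))
    removed_idx = set(
        int(e) for e in rng.choice(n, size=n_remove, replace=False)
    ) if n_remove else set()
    kept = [edges[e] for e in range(n) if e not in removed_idx]
    removed = [edges[e] for e in sorted(removed_idx)]
    existing = {(min(i, j), max(i, j)) for i, j, _ in edges}
    all_pairs = [
        (i, j)
        for i in range(n_proteins)
        for j in range(i + 1, n_proteins)
        if (i, j) not in existing
    ]
    if n_add > len(all_pairs):
        raise ValueError(
            f"cannot add {n_add} edges: only {len(all_pairs)} non-edges exist"
        )
    added = []
    if n_add:
        picks = rng.choice(len(all_pairs), size=n_add, replace=False)
        for p in picks:
            i, j = all_pairs[int(p)]
            y = np.zeros(n_types)
            y[rng.integers(n_types)] = 1.0  # uniform single-type label
            added.append((i, j, y))
    out_edges = kept + added
    flags = np.zeros(len(out_edges), dtype=bool)
    flags[len(kept):] = True
    return PerturbedNetwork(out_edges, flags, removed)
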
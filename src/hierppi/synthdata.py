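"""Synthetic hierarchical PPI data with planted ground truth.

Proteins are self-avoiding 3.8-angstrom C-alpha walks confined to a sphere
(radius ~ length^(1/3)) so the 10-angstrom contact cutoff yields
protein-like contact densities.  Each protein carries a spatially
contiguous feature motif whose class determines, together with the partner's
class, the interaction-type label of every edge — a planted deterministic
rule with zero Bayes error.  The PPI network itself is a stochastic block
model whose communities correlate with the motif classes.

Everything is reproducible from one root seed via spawned NumPy generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .residue_features import STANDARD_AMINO_ACIDS, ResidueFeatureTable
from .structgraph import ProteinGraph, ResidueChain, build_contact_map, featurize_chain
from .tgnn import N_TYPES, PPIDataset

# feature columns carrying the planted motif signal (KOW and TPSA)
MOTIF_COLUMNS = (5, 6)

# sign pattern on (KOW, TPSA) per motif class; cycled if more classes
_CLASS_PATTERNS = ((1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0),
                   (0.0, 1.0), (1.0, 0.0))

# edge-type rule for 3 motif classes: unordered class pair -> 7-bit label.
# Patterns are distinct and each type appears in 2-3 of them, keeping the
# marginal type frequencies roughly balanced.
DEFAULT_RULE_TABLE_3 = {
    (0, 0): (1, 0, 1, 0, 0, 1, 0),
    (0, 1): (0, 1, 0, 1, 0, 0, 1),
    (0, 2): (1, 1, 0, 0, 1, 0, 0),
    (1, 1): (0, 0, 1, 1, 0, 1, 0),
    (1, 2): (1, 0, 0, 1, 1, 0, 1),
    (2, 2): (0, 1, 1, 0, 0, 0, 1),
}


def default_rule_table(n_classes: int) -> dict:
    """A total, deterministic rule table for any class count."""
    if n_classes == 3:
        return dict(DEFAULT_RULE_TABLE_3)
    patterns = list(DEFAULT_RULE_TABLE_3.values())
    table = {}
    p = 0
    for a in range(n_classes):
        for b in range(a, n_classes):
            base = list(patterns[p % len(patterns)])
            if p >= len(patterns):  # rotate to keep patterns distinct
                shift = p // len(patterns)
                base = base[shift:] + base[:shift]
            table[(a, b)] = tuple(base)
            p += 1
    return table


@dataclass
class SyntheticSpec:
    n_proteins: int = 60
    residue_range: tuple = (50, 100)
    bond_length: float = 3.8
    excluded_radius: float = 4.0
    confinement_scale: float = 3.5   # sphere radius = scale * length^(1/3)
    contact_cutoff: float = 10.0
    n_communities: int = 3
    p_in: float = 0.2
    p_out: float = 0.01
    motif_size: int = 6
    motif_offset: float = 6.0        # in standardized feature units
    class_community_coupling: float = 0.8
    rule_table: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.p_in <= self.p_out:
            raise ValueError("require p_in > p_out")
        if self.motif_size >= self.residue_range[0]:
            raise ValueError("motif must be smaller than the shortest chain")
        if self.rule_table is None:
            self.rule_table = default_rule_table(self.n_communities)
        pairs = {
            (a, b)
            for a in range(self.n_communities)
            for b in range(a, self.n_communities)
        }
        if set(self.rule_table) != pairs:
            raise ValueError("rule table must cover every unordered class pair")


def generate_chain(
    length: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    protein_id: str = "synth",
    max_restarts: int = 50,
) -> ResidueChain:
    """Confined self-avoiding walk with fixed 3.8-angstrom bonds."""
    if length < 10:
        raise ValueError("chain length must be >= 10")
    radius = spec.confinement_scale * length ** (1.0 / 3.0)
    b, excl = spec.bond_length, spec.excluded_radius
    for _ in range(max_restarts):
        coords = np.empty((length, 3))
        coords[0] = rng.uniform(-radius / 2, radius / 2, size=3)
        ok = True
        for i in range(1, length):
            placed = False
            for _ in range(100):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = coords[i - 1] + b * d
                if np.linalg.norm(cand) > radius:
                    continue
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if dists.min() < excl:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            codes = rng.choice(STANDARD_AMINO_ACIDS, size=length)
            residues = [
                (i + 1, str(codes[i]), coords[i].copy()) for i in range(length)
            ]
            return ResidueChain(protein_id, "A", residues)
    raise RuntimeError(
        f"self-avoiding walk failed after {max_restarts} restarts (length {length})"
    )


def plant_motif(
    chain: ResidueChain,
    motif_class: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    table: ResidueFeatureTable | None = None,
) -> tuple[ProteinGraph, np.ndarray]:
    """Featurize a chain and plant a spatially contiguous class motif.

    A uniform seed residue plus its nearest 3D neighbors form the motif; on
    the KOW and TPSA columns their values are set to the background column
    mean plus the class's signed offset, so the motif/background mean
    difference equals the configured offset exactly.
    """
    n = len(chain)
    if n <= spec.motif_size:
        raise ValueError("chain shorter than motif size")
    cmap = build_contact_map(chain, spec.contact_cutoff)
    X, _ = featurize_chain(chain, table or ResidueFeatureTable())
    coords = chain.coords
    seed_res = int(rng.integers(n))
    dists = np.linalg.norm(coords - coords[seed_res], axis=1)
    motif = np.sort(np.argsort(dists, kind="stable")[: spec.motif_size])
    background = np.setdiff1d(np.arange(n), motif)
    signs = _CLASS_PATTERNS[motif_class % len(_CLASS_PATTERNS)]
    for col, sign in zip(MOTIF_COLUMNS, signs):
        X[motif, col] = X[background, col].mean() + sign * spec.motif_offset
    graph = ProteinGraph(
        protein_id=chain.protein_id,
        A=cmap.matrix,
        X=X,
        residue_labels=[(s, c) for s, c, _ in chain.residues],
    )
    return graph, motif


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    chains: list
    graphs: list                    # aligned with dataset.proteins
    dataset: PPIDataset
    communities: np.ndarray
    motif_classes: np.ndarray
    motif_sets: list                # residue index arrays, per protein


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full synthetic study: proteins, planted motifs, SBM network, labels."""
    root = np.random.SeedSequence(spec.seed)
    rng_chain, rng_motif, rng_net, rng_class = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    m, k = spec.n_proteins, spec.n_communities
    communities = np.arange(m) % k          # balanced block assignment
    coupled = rng_class.random(m) < spec.class_community_coupling
    motif_classes = np.where(
        coupled, communities, rng_class.integers(0, k, size=m)
    )
    chains, graphs, motif_sets = [], [], []
    lo, hi = spec.residue_range
    for p in range(m):
        length = int(rng_chain.integers(lo, hi + 1))
        chain = generate_chain(length, spec, rng_chain, protein_id=f"P{p:04d}")
        graph, motif = plant_motif(chain, int(motif_classes[p]), spec, rng_motif)
        chains.append(chain)
        graphs.append(graph)
        motif_sets.append(motif)
    edges = []
    for i in range(m):
        for j in range(i + 1, m):
            p = spec.p_in if communities[i] == communities[j] else spec.p_out
            if rng_net.random() < p:
                a, b = sorted((int(motif_classes[i]), int(motif_classes[j])))
                y = np.array(spec.rule_table[(a, b)], dtype=np.float64)
                edges.append((i, j, y))
    if not edges:
        raise RuntimeError("synthetic network is empty; raise p_in/p_out")
    dataset = PPIDataset([f"P{p:04d}" for p in range(m)], edges)
    return SyntheticDataset(
        spec=spec, chains=chains, graphs=graphs, dataset=dataset,
        communities=communities, motif_classes=motif_classes,
        motif_sets=motif_sets,
    )
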
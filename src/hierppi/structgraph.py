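"""Bottom-view graph construction: PDB chain -> contact map + feature matrix.

A protein is reduced to its C-alpha trace.  Residues are nodes; two residues
are in contact when their C-alpha atoms lie within a distance cutoff
(default 10 angstrom, inclusive).  Node features are the seven residue-level
physicochemical properties from :mod:`hierppi.residue_features`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import pdist, squareform

from .residue_features import N_FEATURES, ResidueFeatureTable

DEFAULT_CUTOFF = 10.0


class ChainNotFoundError(KeyError):
    pass


class EmptyChainError(ValueError):
    pass


@dataclass
class ResidueChain:
    """Ordered C-alpha trace of one chain."""

    protein_id: str
    chain_id: str
    residues: list  # (author_seq_number, three_letter_code, xyz ndarray)
    n_missing_ca: int = 0

    def __len__(self):
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r[2] for r in self.residues], dtype=np.float64)

    @property
    def codes(self) -> list:
        return [r[1] for r in self.residues]


@dataclass
class ContactMap:
    matrix: np.ndarray
    cutoff_angstrom: float = DEFAULT_CUTOFF


@dataclass
class ProteinGraph:
    """One protein in the bottom view: contact adjacency + residue features."""

    protein_id: str
    A: np.ndarray  # n x n binary, zero diagonal
    X: np.ndarray  # n x 7
    residue_labels: list = field(default_factory=list)  # (seq_number, code)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def induced_subgraph(self, nodes) -> "ProteinGraph":
        """Node-induced subgraph (used by the explainer)."""
        idx = np.asarray(sorted(nodes), dtype=np.intp)
        return ProteinGraph(
            protein_id=self.protein_id,
            A=self.A[np.ix_(idx, idx)].copy(),
            X=self.X[idx].copy(),
            residue_labels=[self.residue_labels[i] for i in idx],
        )


def _pick_ca_coord(residue):
    """One C-alpha coordinate per residue: altloc 'A', ties by occupancy."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if not atom.is_disordered():
        return np.asarray(atom.coord, dtype=np.float64)
    alts = {a.get_altloc(): a for a in atom.disordered_get_list()}
    if "A" in alts:
        return np.asarray(alts["A"].coord, dtype=np.float64)
    best = max(alts.values(), key=lambda a: (a.get_occupancy() or 0.0))
    return np.asarray(best.coord, dtype=np.float64)


def parse_pdb_calpha(pdb_text: str, chain_id: str, protein_id: str = "") -> ResidueChain:
    """Extract the C-alpha trace of one chain from PDB-format text.

    Residues are ordered by author sequence number (stable for insertion
    codes); residues lacking a C-alpha atom are skipped and counted in
    ``n_missing_ca``.  HETATM selenomethionine (MSE) is accepted.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(
            protein_id or "prot", io.StringIO(pdb_text)
        )
    model = next(structure.get_models())
    chain = next((c for c in model if c.id == chain_id), None)
    if chain is None:
        raise ChainNotFoundError(
            f"chain not found: {chain_id!r} (present: {[c.id for c in model]})"
        )
    entries, missing = [], 0
    for res in chain:
        hetflag, seqnum, icode = res.id
        if hetflag.strip() and hetflag != "H_MSE":
            continue  # skip waters/ligands; keep MSE
        coord = _pick_ca_coord(res)
        if coord is None:
            missing += 1
            continue
        entries.append((seqnum, res.get_resname().strip(), coord))
    if not entries:
        raise EmptyChainError(f"empty chain: no C-alpha atoms in chain {chain_id!r}")
    entries.sort(key=lambda e: e[0])  # stable: insertion codes keep file order
    return ResidueChain(protein_id or "prot", chain_id, entries, missing)


def build_contact_map(chain: ResidueChain, cutoff_angstrom: float = DEFAULT_CUTOFF) -> ContactMap:
    """Binary symmetric contact map at the inclusive distance cutoff."""
    if len(chain) < 2:
        raise ValueError("contact map requires at least 2 residues")
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    coords = chain.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite C-alpha coordinates")
    dist = squareform(pdist(coords))
    A = (dist <= cutoff_angstrom).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return ContactMap(A, cutoff_angstrom)


def featurize_chain(chain: ResidueChain, table: ResidueFeatureTable | None = None):
    """n x 7 feature matrix for a chain.

    Returns ``(X, unmapped_indices)``; residues whose code cannot be mapped
    to a standard amino acid receive the alphabet-mean row and are flagged.
    """
    table = table or ResidueFeatureTable()
    X = np.empty((len(chain), N_FEATURES), dtype=np.float64)
    unmapped = []
    for i, (_, code, _) in enumerate(chain.residues):
        X[i], ok = table.row(code)
        if not ok:
            unmapped.append(i)
    return X, unmapped


def build_protein_graph(
    pdb_text: str,
    chain_id: str,
    cutoff_angstrom: float = DEFAULT_CUTOFF,
    table: ResidueFeatureTable | None = None,
    protein_id: str = "",
) -> ProteinGraph:
    """Parse, contact-map and featurize one chain into a :class:`ProteinGraph`."""
    chain = parse_pdb_calpha(pdb_text, chain_id, protein_id)
    cmap = build_contact_map(chain, cutoff_angstrom)
    X, _ = featurize_chain(chain, table)
    return ProteinGraph(
        protein_id=chain.protein_id,
        A=cmap.matrix,
        X=X,
        residue_labels=[(s, c) for s, c, _ in chain.residues],
    )


def graph_from_chain(
    chain: ResidueChain,
    cutoff_angstrom: float = DEFAULT_CUTOFF,
    table: ResidueFeatureTable | None = None,
) -> ProteinGraph:
    """Same as :func:`build_protein_graph` but starting from a parsed chain."""
    cmap = build_contact_map(chain, cutoff_angstrom)
    X, _ = featurize_chain(chain, table)
    return ProteinGraph(
        protein_id=chain.protein_id,
        A=cmap.matrix,
        X=X,
        residue_labels=[(s, c) for s, c, _ in chain.residues],
    )
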
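"""Text serialization: protein-graph archives, mini-PDB traces, edge tables,
importance profiles and run manifests.

A protein-graph archive is a directory ``<id>.graph/`` holding
``adjacency.tsv`` (sparse triplets i, j, 1 for the upper triangle),
``features.tsv`` (one row per residue, 7 columns) and ``residues.tsv``
(author seq number + three-letter code), plus ``meta.yaml``.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .residue_features import FEATURE_NAMES
from .structgraph import ProteinGraph, ResidueChain
from .tgnn import INTERACTION_TYPES, PPIDataset


def write_graph_archive(graph: ProteinGraph, out_dir) -> Path:
    d = Path(out_dir) / f"{graph.protein_id}.graph"
    d.mkdir(parents=True, exist_ok=True)
    iu, ju = np.nonzero(np.triu(graph.A))
    pd.DataFrame({"i": iu, "j": ju, "v": np.ones(len(iu), dtype=int)}).to_csv(
        d / "adjacency.tsv", sep="\t", index=False
    )
    pd.DataFrame(graph.X, columns=list(FEATURE_NAMES)).to_csv(
        d / "features.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(graph.residue_labels, columns=["seq_number", "code"]).to_csv(
        d / "residues.tsv", sep="\t", index=False
    )
    (d / "meta.yaml").write_text(
        yaml.safe_dump({"protein_id": graph.protein_id, "n_residues": graph.n})
    )
    return d


def read_graph_archive(path) -> ProteinGraph:
    d = Path(path)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    n = int(meta["n_residues"])
    adj = pd.read_csv(d / "adjacency.tsv", sep="\t")
    A = np.zeros((n, n))
    A[adj["i"], adj["j"]] = 1.0
    A = np.maximum(A, A.T)
    X = pd.read_csv(d / "features.tsv", sep="\t").to_numpy(dtype=np.float64)
    res = pd.read_csv(d / "residues.tsv", sep="\t")
    labels = list(zip(res["seq_number"].astype(int), res["code"].astype(str)))
    return ProteinGraph(meta["protein_id"], A, X, labels)


def chain_to_pdb(chain: ResidueChain) -> str:
    """Minimal PDB text with one CA ATOM record per residue."""
    lines = []
    for serial, (seq, code, xyz) in enumerate(chain.residues, start=1):
        lines.append(
            f"ATOM  {serial:>5}  CA  {code:<3} {chain.chain_id}{seq:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_edges_tsv(dataset: PPIDataset, path, edge_indices=None):
    """STRING-style long-format table: one row per (pair, present type)."""
    rows = []
    idx = range(len(dataset.edges)) if edge_indices is None else edge_indices
    for e in idx:
        i, j, y = dataset.edges[e]
        for k in np.flatnonzero(np.asarray(y)):
            rows.append(
                (dataset.proteins[i], dataset.proteins[j], INTERACTION_TYPES[k])
            )
    pd.DataFrame(
        rows, columns=["protein_id_1", "protein_id_2", "interaction_type"]
    ).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> PPIDataset:
    return PPIDataset.from_dataframe(pd.read_csv(path, sep="\t"))


def write_importance_tsv(profile, graph: ProteinGraph, path):
    rows = [
        (seq, code, profile.z_f[i], profile.z_s[i])
        for i, (seq, code) in enumerate(graph.residue_labels)
    ]
    pd.DataFrame(
        rows, columns=["seq_number", "code", "raw_importance", "z_score"]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_manifest(path, command: str, config: dict, seeds: dict,
                   inputs: dict, outputs: dict):
    """Run manifest: everything needed to replay a command."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "code_version": __version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
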
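"""Canned study protocols on the synthetic benchmark.

These functions tie the generator, model, explainer and metrics into the
package's standard evaluation studies: end-to-end learning against a
label-shuffled control, residue-importance recovery of the planted motifs,
robustness to network perturbation, and network-structure recovery by the
heuristic link predictors.  Both the test suite and the results-reproduction
script run these, so the numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasplit import perturb_network, split_random
from .explain import explain_protein, influence_scores
from .model import HierPPI, HierPPIResults
from .netanalysis import heuristic_scores, louvain_labels, recovery_metrics
from .synthdata import SyntheticDataset, SyntheticSpec, generate_dataset
from .tgnn import PPIDataset
from .trainer import TrainConfig

#: training schedule of the scaled-down synthetic study
STUDY_EPOCHS = 200
#: deterministic restarts; the restart with the best validation F1 is kept
STUDY_RESTARTS = 3


@dataclass
class LearningStudy:
    data: SyntheticDataset
    results: HierPPIResults
    heldout_best_f1: float
    heldout_micro_f1: float
    macro_aupr: float | None
    shuffled_best_f1: float
    n_test_edges: int
    train_partners: dict = field(repr=False, default_factory=dict)


def learning_study(
    seed: int,
    epochs: int = STUDY_EPOCHS,
    restarts: int = STUDY_RESTARTS,
    spec: SyntheticSpec | None = None,
) -> LearningStudy:
    """Train on the default synthetic dataset and on a label-shuffled control.

    The shuffled control permutes edge labels over edges (structure intact,
    labels decoupled from the planted classes); its held-out score bounds
    what marginal label statistics alone can achieve.
    """
    spec = spec or SyntheticSpec(seed=seed)
    data = generate_dataset(spec)
    split = split_random(data.dataset.edges, test_fraction=0.2, seed=seed)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    res = HierPPI(data.graphs, data.dataset).fit(
        split=split, config=cfg, restarts=restarts, val_fraction=0.2
    )
    report = res.evaluate()

    rng = np.random.default_rng(seed + 10_000)
    perm = rng.permutation(len(data.dataset.edges))
    shuffled = PPIDataset(
        data.dataset.proteins,
        [(i, j, data.dataset.edges[int(p)][2])
         for (i, j, _), p in zip(data.dataset.edges, perm)],
    )
    res_sh = HierPPI(data.graphs, shuffled).fit(
        split=split, config=cfg, restarts=1
    )
    partners: dict = {}
    for e in res.split.train_edges:
        i, j, _ = data.dataset.edges[e]
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    return LearningStudy(
        data=data,
        results=res,
        heldout_best_f1=report.best_f1,
        heldout_micro_f1=report.micro_f1_at_threshold,
        macro_aupr=report.macro_aupr,
        shuffled_best_f1=res_sh.evaluate().best_f1,
        n_test_edges=len(split.test_edges),
        train_partners=partners,
    )


@dataclass
class ExplainerStudy:
    protein_indices: list
    aucs: np.ndarray
    mean_auc: float
    mean_motif_z: float
    mean_background_z: float


def explainer_study(
    study: LearningStudy,
    n_proteins: int = 20,
    n_samples: int = 200,
    seed: int = 0,
) -> ExplainerStudy:
    """Recover planted motifs from residue importance on the trained model.

    Proteins are ranked by how much their structure influences the model's
    predictions (a model-only statistic: spread of the prediction when the
    protein's graph is substituted by others'); the ``n_proteins`` most
    influential proteins are explained with the partner-averaged profile.
    Reports the ranking AUC of motif vs background residues by z-score.
    """
    res, data = study.results, study.data
    partners = study.train_partners
    queries = [(a, partners[a][0]) for a in sorted(partners)]
    infl = influence_scores(res.net, data.graphs, res.A_msg, queries, seed=seed)
    chosen = sorted(sorted(partners), key=lambda a: -infl[a])[:n_proteins]
    aucs, motif_z, background_z = [], [], []
    for a in chosen:
        prof = explain_protein(
            res.net, data.graphs, res.A_msg, a, partners[a],
            n_samples=n_samples, seed=seed + 1000 * a,
        )
        z = np.nan_to_num(prof.z_s, nan=0.0)
        motif = np.zeros(data.graphs[a].n, dtype=bool)
        motif[data.motif_sets[a]] = True
        # rank-based AUC of motif vs background residues
        order = np.argsort(np.argsort(z))
        n_pos, n_neg = motif.sum(), (~motif).sum()
        auc = (order[motif].sum() - n_pos * (n_pos - 1) / 2) / (n_pos * n_neg)
        aucs.append(float(auc))
        motif_z.append(z[motif].mean())
        background_z.append(z[~motif].mean())
    return ExplainerStudy(
        protein_indices=chosen,
        aucs=np.array(aucs),
        mean_auc=float(np.mean(aucs)),
        mean_motif_z=float(np.mean(motif_z)),
        mean_background_z=float(np.mean(background_z)),
    )


def robustness_study(
    seed: int,
    add_ratio: float = 0.2,
    remove_ratio: float = 0.2,
    epochs: int = STUDY_EPOCHS,
    restarts: int = 1,
    spec: SyntheticSpec | None = None,
) -> float:
    """Held-out best-F1 after training on a perturbed interaction network.

    ``add_ratio`` of spurious edges (random single-type labels) are injected
    and ``remove_ratio`` of true edges deleted before splitting, emulating
    false positives/negatives in interaction databases.  Evaluation uses
    surviving true test edges only (injected edges carry no meaningful
    label to score against).
    """
    spec = spec or SyntheticSpec(seed=seed)
    data = generate_dataset(spec)
    pert = perturb_network(
        data.dataset.edges, data.dataset.m, add_ratio, remove_ratio, seed=seed
    )
    perturbed = PPIDataset(data.dataset.proteins, pert.edges)
    split = split_random(perturbed.edges, test_fraction=0.2, seed=seed)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    res = HierPPI(data.graphs, perturbed).fit(
        split=split, config=cfg, restarts=restarts, val_fraction=0.2
    )
    true_test = [e for e in res.split.test_edges if not pert.is_injected[e]]
    return res.evaluate(true_test).best_f1


@dataclass
class NetworkRecoveryStudy:
    louvain_nmi_planted: float
    heuristics: dict  # method -> (degree_mae, community_nmi)


def network_recovery_study(seed: int, observed_fraction: float = 0.5,
                           spec: SyntheticSpec | None = None) -> NetworkRecoveryStudy:
    """Community detectability of the generated network and heuristic
    link-prediction recovery from a half-observed network."""
    from sklearn.metrics import normalized_mutual_info_score

    spec = spec or SyntheticSpec(seed=seed)
    data = generate_dataset(spec)
    A_true = data.dataset.adjacency()
    nmi_planted = float(normalized_mutual_info_score(
        data.communities, louvain_labels(A_true, seed=seed),
        average_method="arithmetic",
    ))
    obs_split = split_random(data.dataset.edges, 1 - observed_fraction, seed)
    A_obs = data.dataset.adjacency(obs_split.train_edges)
    out = {}
    for method in ("cn", "l3"):
        rec = recovery_metrics(
            A_true, heuristic_scores(A_obs, method), observed=A_obs, seed=seed
        )
        out[method] = (rec.degree_mae, rec.community_nmi)
    return NetworkRecoveryStudy(nmi_planted, out)
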
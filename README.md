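# hierppi

Hierarchical two-view graph learning for multi-type protein–protein
interaction (PPI) prediction, with a built-in residue-importance explainer.

PPIs are naturally hierarchical: inside a protein, residues assemble into
functional sites; between proteins, the interactome forms communities of
densely interacting partners. `hierppi` models both levels at once. Each
protein is a **residue contact-map graph** — nodes at Cα positions, edges
for Cα–Cα distances ≤ 10 Å, seven physicochemical features per residue
(pI, polarity, acid/base class, H-bond acceptors/donors, KOW, TPSA) —
encoded by two GCN blocks

  H⁽ˡ⁺¹⁾ = BN(ReLU(D̃^(−1/2)(A + I)D̃^(−1/2) H⁽ˡ⁾ W⁽ˡ⁾)),  d₁ = d₂ = 128,

followed by a self-attention-pooling readout. The **PPI network** is a
graph over those protein embeddings, encoded by three GIN blocks

  x_v ← BN(ReLU(MLP((1 + ε)·x_v + Σ_{u∈N(v)} x_u))),  MLP width 64,

and a pair (i, j) is classified from h_i ∥ h_j into c = 7 interaction
types (binding, reaction, catalysis, ptmod, inhibition, activation,
expression) with multi-task binary cross-entropy, trained end to end
(Adam, lr 0.001, β₁ = β₂ = 0.99, batch 128). Residue importance for a
predicted interaction is computed without residue labels, by sampling
connected subgraphs G_s of the query protein and scoring each with the
mutual information MI_s = H(Y) − H(Y | G = G_s) between the prediction
and the subgraph; equal shares MI_s/|G_s| averaged per residue and
z-scored give the importance profile z_s.

The package is written against the scientific Python stack (NumPy/SciPy/
pandas/scikit-learn/NetworkX/Biopython) with its own float64 reverse-mode
autodiff core; it needs no GPU.

Audience: computational biologists who want a transparent, fully
inspectable reference implementation of hierarchical PPI learning — for
method study, ablation, and teaching — plus the accompanying toolbox
(contact-map construction from PDB, BFS/DFS out-of-distribution splits,
network perturbation, heuristic link predictors CN/Katz/AA/PA/SimRank/L3,
degree-MAE and Louvain-NMI recovery metrics).

## Worked example

Everything runs on a built-in synthetic benchmark with planted ground
truth: proteins are confined self-avoiding Cα walks carrying a spatially
contiguous 6-residue feature motif; the network is a 3-community
stochastic block model; each edge's 7-bit type label is a fixed
deterministic function of the two motif classes (zero Bayes error).

```python
from hierppi import HierPPI, SyntheticSpec, TrainConfig, generate_dataset
from hierppi.datasplit import split_random

data  = generate_dataset(SyntheticSpec(seed=1))
split = split_random(data.dataset.edges, test_fraction=0.2, seed=1)
model = HierPPI(data.graphs, data.dataset)
res   = model.fit(split=split, config=TrainConfig(epochs=200, seed=1),
                  restarts=3)
print(res.summary())
```

```
        Hierarchical two-view PPI model
====================================================
proteins:             60
interactions:         128
split:                random (test fraction 0.2)
train / test edges:   82 / 26
epochs trained:       200
final training loss:  0.2357
test classes C1/C2/C3: 96.2% / 3.8% / 0.0%
----------------------------------------------------
held-out micro-F1 @0.5:  0.8395
held-out best-F1:        0.8603 (threshold 0.066)
AUPR binding      0.8223
AUPR reaction     0.9797
AUPR catalysis    0.9702
AUPR ptmod        1.0000
AUPR inhibition   0.6250
AUPR activation   0.9403
AUPR expression   0.8933
====================================================
```

The restart selection trained three initializations and kept the one with
the best validation F1, so 82 of the 102 training edges fed the gradient.
Held-out best-F1 of 0.86 against a planted rule (a label-shuffled control
caps at 0.63) shows the model recovered most of the class structure from
structure + network jointly; C1 = 96% means nearly all test pairs had both
proteins seen in training, the regime a random split produces. Per-type
AUPR tracks type prevalence — inhibition is the rarest type in this draw.
Explaining one protein:

```python
prof = res.explain("P0007")          # partner-averaged residue profile
site = prof.predicted_site()         # residues with z_s > 0
```

The profile's `z_s` ranks planted-motif residues above background
(ranking AUC 0.81 averaged over the 20 most influential proteins in the
run above, motif-vs-background z-gap ≈ 1.5).

A command-line interface mirrors the library:

```bash
hierppi simulate --seed 1 --out data/
hierppi train --graphs data/graphs --edges data/edges.tsv \
        --epochs 200 --seed 1 --out run/
hierppi explain --checkpoint run/checkpoint.npz --graphs data/graphs \
        --edges data/edges.tsv --protein P0007 --partner P0012 --out imp.tsv
hierppi linkpred --edges data/edges.tsv --out lp/
```

`build-graphs` constructs contact-map graphs from real PDB files given a
`chains.tsv` mapping (protein id, PDB file, chain).

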
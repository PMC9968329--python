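# Methods

## The model

`hierppi` predicts multi-type protein–protein interactions (PPIs) from a
two-level graph. Every protein is a *residue graph*: nodes are amino-acid
residues located at their Cα atoms, edges connect residues whose Cα–Cα
distance is at most a cutoff (default 10 Å, inclusive), and each node
carries θ = 7 physicochemical features (isoelectric point, polarity,
acid/base class, H-bond acceptor and donor counts, octanol–water partition
coefficient KOW, topological polar surface area TPSA). The PPI network is a
graph over proteins; each undirected edge carries a 7-bit multi-label over
the interaction types (binding, reaction, catalysis, ptmod, inhibition,
activation, expression).

**Bottom view.** Two graph-convolution blocks encode each residue graph:

    H(l+1) = BN( ReLU( D̃^(-1/2) (A + I) D̃^(-1/2) H(l) W(l) ) ),

with output widths d1 = d2 = 128. A self-attention pooling readout scores
nodes with a one-channel graph convolution, keeps the top half
(keep ratio 0.5), gates the kept rows by tanh of their score, and averages
them into one 128-dimensional protein embedding. Batch-norm statistics are
pooled over the nodes of *all* proteins in a batch: per-graph statistics
would subtract each protein's own channel means, which removes exactly the
graph-level signal the readout is meant to summarize. In evaluation mode
batch norm is a frozen affine map, so batched and per-protein encoding
agree bit for bit.

**Top view.** Three GIN blocks propagate the protein embeddings over the
PPI network,

    x_v ← BN( ReLU( MLP( (1 + ε) x_v + Σ_{u∈N(v)} x_u ) ) ),

with two-layer MLPs of width 64 and a learnable ε initialized at 0. A pair
(i, j) is classified from the concatenation h_i ∥ h_j by a single fully
connected layer with 7 logits; because concatenation is ordered, training
uses both orderings of every pair and inference averages the two logit
vectors, making predictions exactly symmetric.

**Training.** The loss is multi-task binary cross-entropy summed over the
7 types; for optimization it is averaged over the pairs of a batch so the
gradient scale is batch-size independent. Adam with lr = 0.001,
β1 = β2 = 0.99, batch size 128, computed from logits in the stable
log-sum-exp form. By default message passing uses the training-edge
adjacency only (leak-free); a full-graph mode exists for transductive use.
All computation is float64 NumPy under a small reverse-mode autodiff core
written for this package; gradient correctness is verified against central
finite differences in the test suite.

**Restart selection.** A single optimization run on a ~100-edge training
set is high-variance. `HierPPI.fit(restarts=k)` therefore trains k
deterministic restarts and keeps the one with the best micro-best-F1 on a
validation subset carved out of the *training* edges (test edges are never
consulted). The standard synthetic study uses k = 3 with a 20% validation
carve-out; the default remains a single run.

## Residue importance (explainer)

For a query pair, a random connected subgraph G_s of the query protein is
scored by the mutual information MI_s = H(Y) − H(Y | G = G_s), where Y is
the model's Bernoulli prediction and the conditional term re-encodes the
protein restricted to G_s (node-induced subgraph, features and contacts
restricted; everything downstream re-propagated). Entropies are in nats
with probabilities clipped at 1e-12. Subgraphs grow by random traversal
from a uniform root to a uniform size in [max(2, 0.1 n), 0.5 n]; the
default is 200 samples. Every member of G_s receives the equal share
MI_s / |G_s|; a residue's raw importance z_f is the mean of its shares over
the samples containing it, and the reported profile is the z-score
z_s = (z_f − μ)/σ (population σ; all-zero with a flag when σ = 0).

Which prediction to explain matters. With multi-label redundancy, the
highest-probability type of a pair is often one the query protein does not
influence at all — its importance landscape is then pure noise. Three
options are provided: an explicit type index, the highest-probability type
(`explain_pair` default), and the most *sensitive* type (largest MI spread
over the samples). The protein-level summary `explain_protein` scores each
subgraph sample with the total MI summed over all 7 types (the information
the subgraph carries about the joint presence prediction; insensitive
types contribute ≈ 0) and averages standardized profiles over all of the
protein's interaction partners. The synthetic explainer study additionally
ranks proteins by a model-only influence statistic — the spread of the
pair prediction when the query protein's graph is substituted by other
proteins' graphs — and explains the most influential proteins, since a
protein whose substitution leaves predictions unchanged has no
residue-level story to extract.

## Synthetic data

The generator emulates the shape of a structure-annotated PPI dataset at
desk scale. Proteins are self-avoiding walks with exact 3.8 Å bonds,
≥ 4.0 Å non-bonded separation, confined to a sphere of radius
3.5 · L^(1/3) Å — at the 10 Å cutoff this yields protein-like mean contact
degrees (~16). Each protein carries a planted *motif*: the 6 residues
nearest a random seed residue get class-specific values on the KOW and
TPSA columns (background mean ± 6 standardized units). The network is a
3-block stochastic block model (p_in = 0.2, p_out = 0.01, 60 proteins);
the motif class equals the community with probability 0.8 and is uniform
otherwise. Edge labels are a fixed deterministic rule table mapping the
unordered class pair to a 7-bit pattern, so labels are exactly recoverable
from the planted classes (zero Bayes error).

The coupling of 0.8 and offset of 6 standardized units were calibrated so
the study exercises both routes the architecture offers: with full
class–community coupling the network topology alone determines the labels
and a model need never read residue features; with weak coupling the
feature route is not learnable within the 200-epoch scaled-down schedule.
The chosen point keeps topology informative but imperfect, forcing the
trained model to consult residue features — the regime the residue-level
explainer needs.

What the generator does *not* emulate: real secondary structure or
sequence–structure consistency, degree heterogeneity of the interactome
(hubs), assay-specific label noise, and homologous proteins. Passing the
synthetic studies shows the machinery is correct and that the architecture
can learn planted structure–function rules at small scale; it does not
certify accuracy on real interactomes.

## Study sizes, schedules, and known limitations

The standard synthetic study trains 200 epochs on ~80 training edges over
60 proteins of 50–100 residues (about two minutes per run on one CPU), with
3 restarts; the robustness study (20% injected + 20% removed edges) uses
single runs over 3 seeds; the explainer study uses 200 subgraph samples
per (protein, partner) query over the 20 most influential proteins.

Two behaviors of the scaled-down regime are worth knowing. First,
single-run training is noisy: held-out best-F1 varies by ±0.05 or more
across restarts, which is why restart selection is part of the standard
protocol. Second, *how much* a trained model relies on residue features —
as opposed to the redundant network-topology route — varies across
equally-accurate optima; the explainer faithfully reports the model it is
given, so motif-recovery AUC inherits that variance. At full scale
(thousands of edges, tens of thousands of optimizer steps) the two routes
have time to reconcile; at desk scale explainer quality should be read as
a property of the particular fitted model, not of the method alone.

Numerical choices: inclusive distance cutoff; altloc 'A' kept (ties by
occupancy); residues lacking a Cα are skipped and counted; insertion-coded
residues sort stably after their base number; unknown residue codes get
the alphabet-mean feature row and a flag; Katz uses the matrix closed form
when the spectral radius of βA is below 1 and a length-5 truncated series
otherwise; SimRank iterates to 1e-4 with decay 0.8; NMI uses arithmetic
normalization; fractional counts round half-even; ties in the best-F1
threshold sweep resolve to the lowest threshold; top-k pooling ties break
by node index.
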
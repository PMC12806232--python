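# Methods

## Problem and model

Given drugs with (a) a molecular structure (SMILES) and (b) four binary
bind-protein annotation vectors (transporters, carriers, enzymes, targets),
and a table of drug pairs each labeled with one of *E* interaction event
types, the task is *E*-way classification of held-out pairs.  There is no
negative class: as in the source datasets this framing derives from, only
interacting pairs are recorded, and the softmax head emits a distribution
over event types.  Pairs are unordered; both orientations are set in every
adjacency matrix and the head always sees the canonical order *i < j*, so
no orientation inconsistency can arise.

The pipeline has four stages.

**Structure encoder.**  A message-passing network over the heavy-atom
graph.  Initial states come from a learnable embedding table keyed by
element symbol (shared across molecules — per-molecule random vectors would
make inference non-deterministic).  Each of *T* steps computes messages
m_v = Σ_{w∈N(v)} W h_w with one shared matrix per step (optionally one per
bond type, or tied across steps), then updates states through two sigmoid
gates in the highway-network style: a carry gate on the previous state and
a fuse gate on the incoming message, both conditioned on the concatenation
h_v ⊕ m_v.  The readout is a soft-attention node sum over h⁰_v ⊕ h^T_v
(sigmoid attention score × tanh value).  It is permutation invariant and
additive over disjoint node sets, both of which are asserted in tests.  A
per-pair message matrix indexed by the two endpoint atoms would not be
learnable across molecules, hence the shared-per-step choice.

**Bind-protein encoder.**  Raw annotation vectors are long and sparse, so
the per-drug feature is relational: per entity class, the drug–drug Jaccard
matrix (defined as 0 when both vectors are empty — no shared annotations is
no evidence of similarity, and 0/0 must not mint unit similarity between
unannotated drugs), compressed by PCA to D columns per class.  The PCA sign
is fixed by making each component's largest-magnitude loading positive, so
results are bit-reproducible.  PCA is fitted on the full similarity matrix:
the similarities contain no event labels, so this is leakage-free.  The
four compressed rows are concatenated (4D) and passed through an
autoencoder; the encoder is 4D → hidden (ReLU) → single-head scaled
dot-product self-attention over the four entity-class blocks of the hidden
layer → output E_i, with a mirror-image decoder.  The reconstruction MSE
enters the training loss with weight λ (default 0.1), i.e. the autoencoder
is trained jointly rather than pre-trained — one optimizer loop, and the
embedding stays adapted to the classification task.

**Meta-path network.**  The candidate relations form an adjacency stack:
one symmetric 0/1 subgraph per event type built from *training* pairs only,
two feature-similarity graphs, and the identity matrix (so length-1
meta-paths stay expressible; the similarity graphs' diagonals are forced to
zero so self-connectivity enters the stack exactly once).  The similarity
graphs are thresholded K-head weighted cosine graphs over the structure and
bind-protein embeddings (threshold ε = 0.5, the midpoint of its admissible
range; K = 2 heads; the head weights are trained jointly, and the graphs
are recomputed inside the autodiff graph on every forward pass, which at
the package's desk-scale batch sizes means once per epoch).  Each of C
channels learns a subgraph as the product of L softmax-selected convex
combinations of the stack; after every product the running matrix is
normalized by its degree matrix, A_l = D⁻¹ A_i A_j (row normalization
exactly as printed, not the symmetric D^{-1/2}AD^{-1/2} variant), with
zero-degree rows passed through unchanged.  Row normalization telescopes —
normalizing after each factor equals normalizing the raw product once — so
the layer loop starts from I and the two-factor result matches the
closed-form D⁻¹A_{t1}A_{t2} oracle to machine precision.  A shared-weight
graph convolution σ(D⁻¹ A_l X W) with X = E′ ⊕ E and σ = ReLU runs on every
channel; channel outputs are concatenated.

The selection logits are initialized with a +4 bias on the identity slot
(≈ 0.9 softmax weight over a six-member stack).  With a near-uniform start
every channel is a blend of all relations, which smears the node features
over noisy graphs and leaves the whole model far harder to optimize; the
biased start makes each channel begin as plain feature propagation and
move weight onto event or similarity relations only where doing so lowers
the loss.  Selection weights after training are exposed as
`selection_weights_` and the learned subgraphs can be exported as edge
lists for inspection.

**Head and training.**  Two dense layers on Ê′_i ⊕ Ê′_j with a softmax
output.  Cross-entropy plus λ times the reconstruction MSE is minimized by
Adam (library default lr 0.001, cap 1500 epochs, early-stopping patience 10
— the reference configuration; the desk-scale experiments below raise lr to
0.01 and cap at 100–300 epochs).  A 10 % validation split is carved from
the training triples for epoch-level early stopping, and the best-
validation parameters are restored.  The event subgraphs are built from the
gradient-training triples only — neither validation nor held-out edges
enter the stack, so labels cannot leak through the graph structure (the
drug *nodes* are transductive; the held-out information is the labeled
pair).  Training is deterministic under `random_state` in single-threaded
NumPy.

**Ablations.**  `ablate_f` keeps the two feature extractors and the head
(no meta-path network); `ablate_d` keeps the meta-path network and head but
replaces the extractors with a learnable per-drug embedding table (its two
halves stand in for E′ and E when building the similarity graphs).

**Cross-validation** is 5-fold by default over *pairs* (triples), not
drugs, matching the lineage of the datasets this model family is evaluated
on; drug-wise (cold-start) splitting would be a different, harder protocol
and is out of scope.  Metrics are accuracy, macro F1, and one-vs-rest
macro-averaged AUC and AUPR (micro averaging is exposed as an option);
event types absent from a test fold are skipped in the macro mean.

## Numerical core

All neural components run on a small in-package reverse-mode autodiff
engine over float64 NumPy arrays (tape-based, with broadcasting-aware
gradients) and an Adam optimizer.  Sigmoids use `scipy.special.expit`;
softmax and log-softmax are max-shifted.  Gradients of the composite graph
are verified against central finite differences to 1e-7 in the test suite.
One practical consequence of soft selection: a "one-hot" selection realized
by large finite logits leaks exp(−Δ) weight onto every other stack member,
and row normalization can amplify that leakage on rows where the selected
matrix is zero; tests and oracles therefore use logit gaps large enough to
underflow (exp(−2000) = 0), making the selection exactly one-hot.

## Synthetic data

The generator emulates the three input tables with planted, recoverable
structure; everything is deterministic under a seed.

* **Molecules**: random trees (plus an occasional ring) over C/N/O/S under
  valence caps, all single bonds, emitted as SMILES and verified to parse
  back.  Sizes 6–14 atoms.  Molecules carry no label signal by default; the
  structure branch is tested through invariants (permutation invariance,
  additivity), not learnability.
* **Descriptors**: each latent drug cluster owns one disjoint block of bits
  per entity class (lengths 60/42/81/120, divisible by the default three
  clusters); drugs inherit their cluster's pattern with per-bit flip
  probability `descriptor_noise` (defaults to `noise_rate`).  At zero noise
  within-cluster Jaccard is exactly 1 and cross-cluster exactly 0.
* **Events**, three rules, with a `noise_rate` fraction of labels resampled
  uniformly:
  - `cluster_pair` — the event is a fixed function of the unordered cluster
    pair; bind-protein similarity is sufficient to solve the task.
  - `metapath` — a hidden relation graph is drawn as a stochastic block
    model over hidden communities (independent of the descriptor clusters);
    the event of a pair is the sum, mod E, of the two dominant communities
    in its 2-hop co-neighborhood (the set of common neighbors), and pairs
    with an empty co-neighborhood do not interact.  Same-community pairs
    have nearly pure co-neighborhoods (event ≈ 2h mod E) and cross pairs an
    even endpoint mix (event ≈ h_i + h_j mod E), so per-drug label
    marginals are approximately flat and the signal is irreducibly
    pair-level graph structure.  A brute-force 2-hop classifier recomputing
    the rule from the hidden graph scores 1.0 on noiseless labels.
  - `random` — uniform labels; a negative control.

What the generator does **not** emulate: real event-type frequency skew
(DrugBank-derived corpora are heavy-tailed over dozens of event types),
chemically meaningful structure–activity relations, annotation sparsity
patterns, or dataset-scale drug counts.  Passing the synthetic experiments
therefore shows the machinery is correct and can recover the planted kinds
of signal at small scale; it does not certify accuracy on real corpora.

## Desk-scale experiments

The standing experiments (in `ddievent.experiments`) use a reduced
configuration — feature dimension 32, PCA dimension 16 per class,
autoencoder hidden 64, head hidden 64, lr 0.01, 2-fold CV — chosen so each
run takes seconds to a few minutes on one CPU core; the architecture is
unchanged from the reference configuration.

* **Learnability**: 60 drugs, 3 clusters, 3 events, 5 % noise,
  `cluster_pair`, ≤ 100 epochs: mean CV accuracy ≥ 0.9 (the noise ceiling
  is ≈ 0.97).
* **Selection recovery**: a stack with one informative relation R, two
  density-matched random distractors, and I; node labels are the argmax of
  a random linear map of features propagated by D⁻¹RR, with feature width
  (6) far below the node count (160) so no wrong selection can fit them.
  Because softmax selection is non-convex and can lock onto a distractor
  early (a local minimum with visibly higher training loss), each seed runs
  3 random restarts and keeps the lowest-loss run; the first-layer weight
  on R exceeds 0.9 in the majority of seeds.
* **Ablation direction**: on `metapath`-rule data the full model's mean CV
  accuracy is at least the feature-only ablation's in the majority of
  seeds.  This experiment raises the feature dimension to 64 (making the
  graph convolution a square, near-lossless map, so the comparison is not
  dominated by a width bottleneck) and the atom-embedding init scale to 1.0
  (structure embeddings then act as per-drug node signatures, which is what
  graph propagation needs when only the interaction graph is informative),
  and sets λ = 0 for both arms to isolate the meta-path network.  The
  margin is honest but small at this scale: both arms sit well below the
  planted ceiling, and individual seeds can invert.
* **Negative control**: random-rule labels; CV accuracy must stay within
  0.1 of the maximum class prior.  Because held-out edges never enter the
  adjacency stack, there is no route for label leakage, and the model stays
  at the prior.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_dim` | 256 | node feature dimension (structure and bind embeddings; 32–64 in desk runs) |
| `T` (`n_message_steps`) | 3 | message-passing rounds |
| `pca_dim` (D) | 64 | PCA columns per entity class; 4D is the autoencoder input |
| `n_layers` (L) | 2 | meta-path factors per channel (meta-path length) |
| `n_channels` (C) | 3 | independently learned subgraphs |
| `epsilon` | 0.5 | similarity-graph edge threshold in [0, 1] |
| `n_cosine_heads` (K) | 2 | weighted-cosine heads in the similarity graphs |
| `lambda_recon` | 0.1 | weight of the autoencoder reconstruction loss |
| `lr` / `max_epochs` / `patience` | 0.001 / 1500 / 10 | reference optimizer settings |
| `batch_size` | 512 | pairs per Adam step (full-batch at desk scale) |
| `val_fraction` | 0.1 | early-stopping split carved from training triples |
| `atom_embed_scale` | 0.1 | std of initial atom embeddings (node-signature strength) |
| `mode` | `full` | `full`, `ablate_f`, `ablate_d` |

## Degenerate inputs and tie-breaks

Zero-degree rows of any product matrix stay zero through normalization;
all-zero embedding rows get cosine 0; double-zero Jaccard is 0; an event
type with no training pairs keeps an all-zero matrix at its stack slot; an
empty molecule is an error at the readout.  PCA component signs follow the
largest-|loading|-positive convention.  Event labels are re-coded densely
in order of first appearance.  The checkpoint format is a versioned `.npz`
(JSON metadata plus parameter arrays) that must be re-attached to its
dataset on load.

## Known limitations

The engine is dense NumPy: cost grows as O(N_d²) in drugs and O(total
atoms²) in the packed molecular graph, which is fine for hundreds of drugs
but would need sparse matmuls well before the thousands.  The similarity
graphs are recomputed per forward pass, which is part of that quadratic
cost.  Training the full pipeline is sensitive to the scale of the node
features (see `atom_embed_scale`); this is a genuine property of feeding
the head only graph-convolved features rather than a removable artifact.
Pair-level quantities that are bilinear in node identity (e.g. exact
common-neighbor counts) are only approximable by the MLP head on
concatenated node embeddings — a structural limit shared with the model
family this package implements.
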
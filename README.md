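# ddievent

Multi-class prediction of drug–drug interaction (DDI) **events** — the
specific pharmacological consequence of co-administering two drugs (one of
*E* event types), not merely whether the drugs interact.  The package is
aimed at computational drug-safety researchers who have, for each drug, a
SMILES structure and binary bind-protein annotations (transporters,
carriers, enzymes, targets), plus a table of known event-labeled drug
pairs, and who want a trainable, inspectable event classifier together with
fully synthetic benchmarks that exercise every part of the pipeline without
any external download.

## Model

For drugs *i, j* with molecular graphs *G_i(V, E)* and bind-protein bit
vectors *x_i*, the pipeline is:

1. **Structure encoder** — a gated message-passing network over atoms and
   bonds.  States start from a learnable per-element embedding table; for
   *T* steps,

       m_v = Σ_{w∈N(v)} W h_w,
       h_v ← C(W_c, h_v ⊕ m_v) ⊙ h_v + F(W_f, h_v ⊕ m_v) ⊙ m_v,

   with sigmoid carry gate *C* and fuse gate *F*, followed by an attentive
   readout E′_i = Σ_v σ(W₁[h⁰_v ⊕ h^T_v]+b₁) ⊙ tanh(W₂[h⁰_v ⊕ h^T_v]+b₂),
   which is permutation invariant and additive over disjoint fragments.
2. **Bind-protein encoder** — per entity class, the drug–drug Jaccard
   similarity J(x_i, x_j) = |x_i ∩ x_j| / |x_i ∪ x_j|, PCA-compressed to
   *D* columns; the four compressed rows pass through an autoencoder whose
   encoder applies one scaled-dot-product self-attention layer over the
   four entity-class blocks before its output E_i (the decoder's
   reconstruction MSE is an auxiliary loss).
3. **Meta-path network** — the adjacency stack 𝒜 holds one 0/1 subgraph
   per event type (training edges only), two thresholded *K*-head weighted
   cosine similarity graphs built from E′ and E, and the identity A₀ = I.
   Each of *C* channels learns a meta-path subgraph as a product of *L*
   softmax-selected convex combinations of the stack, row-normalized after
   every product, A_l = D⁻¹ A_i A_j; a shared graph convolution
   σ(D⁻¹ A_l X W) with X = E′ ⊕ E runs per channel and the channel outputs
   are concatenated into Ê′.
4. **Pair head** — ŷ_ij = softmax(W₄ ReLU(W₃ [Ê′_i ⊕ Ê′_j] + b₃) + b₄),
   trained with cross-entropy (+ λ·reconstruction MSE) by Adam, with
   epoch-level early stopping on a validation split.

Ablation modes mirror the model's two halves: `ablate_f` drops the
meta-path network (the head consumes X directly) and `ablate_d` replaces
both feature extractors with a learnable per-drug embedding table.

## Worked example

```python
from ddievent import (DDIEventClassifier, SyntheticSpec, assign_folds,
                      cross_validate, generate_dataset)

spec = SyntheticSpec(n_drugs=60, n_events=3, n_clusters=3,
                     noise_rate=0.05, label_rule="cluster_pair", seed=1)
dataset, truth = generate_dataset(spec)        # SMILES + bits + triples
assign_folds(dataset, k=2, seed=1)

clf = DDIEventClassifier(n_dim=32, pca_dim=16, ae_hidden=64, mlp_hidden=64,
                         lr=0.01, max_epochs=100, patience=30, random_state=1)
report, models = cross_validate(clf, dataset, verbose=True)
print(f"mean: acc={report.acc:.4f} f1={report.f1:.4f} "
      f"auc={report.auc:.4f} aupr={report.aupr:.4f}")
```

prints

```
fold 0: acc=0.9600 f1=0.9577 auc=0.9730 aupr=0.9529
fold 1: acc=0.9533 f1=0.9522 auc=0.9577 aupr=0.9122
mean: acc=0.9567 f1=0.9549 auc=0.9654 aupr=0.9325
```

The synthetic labels are a fixed function of latent drug clusters with 5 %
resampling noise, so ~0.95 cross-validated accuracy means the model has
recovered essentially all of the planted rule (the noise ceiling is ~0.97).
The trained estimator exposes `selection_weights_` — the per-channel,
per-layer softmax weights over the adjacency stack — showing which
relations each learned meta-path uses.

A CLI mirrors the library for shell use:

```bash
ddievent simulate --out data/ --n-drugs 60 --label-rule cluster_pair --seed 1
ddievent train --data data/ --n-dim 32 --max-epochs 100 --checkpoint model.npz
ddievent evaluate --data data/ --folds 5 --n-dim 32
ddievent predict --data data/ --checkpoint model.npz --pairs pairs.csv --out preds.csv
ddievent sweep --data data/ --n-trials 10 --out sweep.csv
```

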
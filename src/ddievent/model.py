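"""Pair-level DDI event classifier: estimator, trainer, cross-validation.

:class:`DDIEventClassifier` is a scikit-learn-style estimator over an
:class:`~ddievent.data.EventDataset`.  ``fit`` assembles the full pipeline —
gated MPNN structure embeddings E', bind-protein autoencoder embeddings E,
node features X = E' (+) E, feature-similarity graphs, the adjacency stack,
C soft-selected meta-path subgraphs with a shared GCN — and trains the whole
thing end to end with Adam on cross-entropy over labeled pairs (plus a
weighted autoencoder reconstruction term), with epoch-level early stopping on
a validation split carved from the training triples.  ``predict_proba``
re-runs the forward pass with the learned parameters on any list of drug
pairs.

Ablation modes: ``ablate_f`` keeps only the two feature extractors and the
MLP head (no meta-path network); ``ablate_d`` drops the feature extractors
and feeds a learnable per-drug embedding table into the meta-path network.

Event subgraphs in the adjacency stack are built from the gradient-training
triples only — validation and held-out pairs never enter the stack, so no
label can leak through the graph structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .autodiff import Adam, Tensor, as_tensor, concat
from .bind_protein import (AutoencoderParams, autoencoder_reconstruction_loss,
                           compress_similarities, encode_bind_protein)
from .data import EventDataset, build_event_subgraphs
from .metapath import (MetaPathParams, SimilarityGraphParams,
                       feature_similarity_graph, run_metapath_network)
from .metrics import MetricsReport, evaluate
from .mpnn import MPNNParams, ReadoutParams, encode_structures

MODES = ("full", "ablate_f", "ablate_d")


@dataclass
class MLPParams:
    """Two-layer prediction head: 2*C*n_dim -> hidden -> E."""

    W3: Tensor
    b3: Tensor
    W4: Tensor
    b4: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int,
             n_events: int) -> "MLPParams":
        s3 = np.sqrt(6.0 / (in_dim + hidden))
        s4 = np.sqrt(6.0 / (hidden + n_events))
        return cls(
            W3=Tensor(rng.uniform(-s3, s3, (hidden, in_dim)), requires_grad=True),
            b3=Tensor(np.zeros(hidden), requires_grad=True),
            W4=Tensor(rng.uniform(-s4, s4, (n_events, hidden)), requires_grad=True),
            b4=Tensor(np.zeros(n_events), requires_grad=True),
        )

    def parameters(self) -> list:
        return [self.W3, self.b3, self.W4, self.b4]


def predict_pair(emb_i, emb_j, mlp: MLPParams) -> Tensor:
    """softmax(W4 ReLU(W3 [E_i (+) E_j] + b3) + b4); rows sum to 1.

    Accepts single embeddings (1-D) or batches (2-D, one pair per row).
    """
    ei, ej = as_tensor(emb_i), as_tensor(emb_j)
    squeeze = ei.ndim == 1
    if squeeze:
        ei, ej = Tensor(ei.data[None, :]), Tensor(ej.data[None, :])
    feats = concat([ei, ej], axis=1)
    if feats.shape[1] != mlp.W3.shape[1]:
        raise ValueError("pair feature / MLP dimension mismatch")
    logits = (feats @ mlp.W3.T + mlp.b3).relu() @ mlp.W4.T + mlp.b4
    probs = logits.softmax(axis=1)
    return probs[0] if squeeze else probs


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = logits.log_softmax(axis=1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


class DDIEventClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end multi-class DDI event predictor.

    Parameters mirror the training configuration: ``n_dim`` is the node
    feature dimension (256 in the reference configuration; use smaller values
    at desk scale), ``n_layers``/``n_channels`` the meta-path depth and
    channel count, ``pca_dim`` the per-entity-class PCA width D,
    ``n_message_steps`` the MPNN step count T, ``epsilon`` the similarity-
    graph edge threshold, ``lambda_recon`` the autoencoder loss weight, and
    ``mode`` one of ``full``/``ablate_f``/``ablate_d``.
    """

    def __init__(self, n_dim=256, pca_dim=64, n_layers=2, n_channels=3,
                 n_message_steps=3, n_cosine_heads=2, epsilon=0.5,
                 ae_hidden=None, mlp_hidden=512, lr=0.001, max_epochs=1500,
                 patience=10, batch_size=512, lambda_recon=0.1,
                 val_fraction=0.1, mode="full", bond_typed=False,
                 tied_steps=False, atom_embed_scale=0.1, random_state=0):
        self.n_dim = n_dim
        self.pca_dim = pca_dim
        self.n_layers = n_layers
        self.n_channels = n_channels
        self.n_message_steps = n_message_steps
        self.n_cosine_heads = n_cosine_heads
        self.epsilon = epsilon
        self.ae_hidden = ae_hidden
        self.mlp_hidden = mlp_hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.lambda_recon = lambda_recon
        self.val_fraction = val_fraction
        self.mode = mode
        self.bond_typed = bond_typed
        self.tied_steps = tied_steps
        self.atom_embed_scale = atom_embed_scale
        self.random_state = random_state

    # ------------------------------------------------------------- assembly
    def _init_params(self, rng, n_drugs, n_events, stack_size):
        p = {}
        if self.mode != "ablate_d":
            p["mpnn"] = MPNNParams.init(rng, self.n_dim, self.n_message_steps,
                                        tied=self.tied_steps,
                                        bond_typed=self.bond_typed,
                                        embed_scale=self.atom_embed_scale)
            p["readout"] = ReadoutParams.init(rng, self.n_dim)
            hidden = self.ae_hidden or 8 * self.pca_dim
            p["ae"] = AutoencoderParams.init(rng, 4 * self.pca_dim, hidden,
                                             self.n_dim)
        else:
            p["node_table"] = Tensor(
                0.1 * rng.standard_normal((n_drugs, 2 * self.n_dim)),
                requires_grad=True)
        if self.mode != "ablate_f":
            p["sim_struct"] = SimilarityGraphParams.init(
                rng, self.n_dim, self.n_cosine_heads, self.epsilon)
            p["sim_bind"] = SimilarityGraphParams.init(
                rng, self.n_dim, self.n_cosine_heads, self.epsilon)
            p["metapath"] = MetaPathParams.init(
                rng, stack_size, self.n_channels, self.n_layers,
                2 * self.n_dim, self.n_dim, identity_slot=-1)
            head_in = 2 * self.n_channels * self.n_dim
        else:
            head_in = 2 * 2 * self.n_dim
        p["mlp"] = MLPParams.init(rng, head_in, self.mlp_hidden, n_events)
        return p

    def _all_params(self):
        out = []
        for v in self.params_.values():
            out.extend(v.parameters() if hasattr(v, "parameters") else [v])
        return out

    def _node_features(self):
        """(X, recon_loss) for the current parameters; recon_loss may be None."""
        p = self.params_
        if self.mode == "ablate_d":
            return p["node_table"], None
        E_s = encode_structures(self._graphs, p["mpnn"], p["readout"])
        E_b = encode_bind_protein(self._bind_feat, p["ae"])
        X = concat([E_s, E_b], axis=1)
        recon = autoencoder_reconstruction_loss(Tensor(self._bind_feat), p["ae"])
        return X, recon

    def _forward(self, pairs: np.ndarray):
        """Logits for an array of (i, j) pairs; returns (logits, recon_loss)."""
        p = self.params_
        X, recon = self._node_features()
        if self.mode == "ablate_f":
            node_emb = X
        else:
            half = X.shape[1] // 2
            S1 = feature_similarity_graph(X[:, :half], p["sim_struct"])
            S2 = feature_similarity_graph(X[:, half:], p["sim_bind"])
            stack = list(self._event_mats) + [S1, S2, np.eye(X.shape[0])]
            node_emb = run_metapath_network(stack, X, p["metapath"])
        feats = concat([node_emb[pairs[:, 0]], node_emb[pairs[:, 1]]], axis=1)
        logits = (feats @ p["mlp"].W3.T + p["mlp"].b3).relu() \
            @ p["mlp"].W4.T + p["mlp"].b4
        return logits, recon

    # ------------------------------------------------------------- training
    def fit(self, dataset: EventDataset, train_triples=None):
        """Train on ``train_triples`` (default: all of the dataset's triples)."""
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        triples = list(train_triples if train_triples is not None else dataset.triples)
        if not triples:
            raise ValueError("no training triples")
        rng = np.random.default_rng(self.random_state)

        self._dataset = dataset
        if self.mode != "ablate_d":
            self._graphs = [d.graph() for d in dataset.drugs]
            comp = compress_similarities(dataset, self.pca_dim)
            self._bind_feat = np.concatenate([comp[c] for c in comp], axis=1)

        # canonical unordered pairs, labels
        arr = np.array([(min(i, j), max(i, j), e) for i, j, e in triples])
        perm = rng.permutation(len(arr))
        n_val = int(round(self.val_fraction * len(arr)))
        n_val = min(n_val, len(arr) - 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        tr_pairs, tr_y = arr[tr_idx, :2], arr[tr_idx, 2]
        val_pairs, val_y = arr[val_idx, :2], arr[val_idx, 2]

        grad_triples = [tuple(t) for t in arr[tr_idx]]
        stack = build_event_subgraphs(dataset, grad_triples)
        self._event_mats = stack.matrices[:-1]  # identity re-appended in _forward
        self.stack_tags_ = stack.tags[:-1] + ["sim_structure", "sim_bind", "identity"]

        self.n_events_ = dataset.n_events
        self.classes_ = np.arange(dataset.n_events)
        self.params_ = self._init_params(rng, dataset.n_drugs, dataset.n_events,
                                         len(self.stack_tags_))
        params = self._all_params()
        opt = Adam(params, lr=self.lr)

        best_val = np.inf
        best_snapshot = None
        bad_epochs = 0
        self.loss_history_, self.val_history_ = [], []
        n_tr = len(tr_pairs)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_losses = []
            for start in range(0, n_tr, self.batch_size):
                batch = order[start:start + self.batch_size]
                logits, recon = self._forward(tr_pairs[batch])
                loss = _cross_entropy(logits, tr_y[batch])
                if recon is not None and self.lambda_recon > 0:
                    loss = loss + self.lambda_recon * recon
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            self.loss_history_.append(float(np.mean(epoch_losses)))
            if n_val:
                logits, _ = self._forward(val_pairs)
                vloss = float(_cross_entropy(logits, val_y).data)
                self.val_history_.append(vloss)
                if vloss < best_val:
                    best_val = vloss
                    best_snapshot = [p.data.copy() for p in params]
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break
        if best_snapshot is not None:
            for p, saved in zip(params, best_snapshot):
                p.data = saved
        self.n_epochs_ = len(self.loss_history_)
        if self.mode != "ablate_f":
            self.selection_weights_ = self.params_["metapath"].selection_weights()
        return self

    # ------------------------------------------------------------ inference
    def predict_proba(self, pairs) -> np.ndarray:
        """Event probabilities for (i, j) drug-index pairs, canonical order i<j."""
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")
        pairs = np.asarray([(min(i, j), max(i, j)) for i, j in np.asarray(pairs)[:, :2]])
        logits, _ = self._forward(pairs)
        return logits.softmax(axis=1).data

    def predict(self, pairs) -> np.ndarray:
        return self.classes_[self.predict_proba(pairs).argmax(axis=1)]

    def score(self, pairs, y) -> float:
        return float(np.mean(self.predict(pairs) == np.asarray(y)))


    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Write a self-describing checkpoint (.npz: metadata + arrays)."""
        import json

        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")
        meta = {
            "format_version": 1,
            "estimator_params": self.get_params(),
            "n_events": int(self.n_events_),
            "n_drugs": int(self._dataset.n_drugs),
            "stack_tags": self.stack_tags_,
        }
        arrays = {f"param_{k}": p.data for k, p in enumerate(self._all_params())}
        arrays["event_mats"] = np.stack(self._event_mats) if self._event_mats \
            else np.zeros((0, self._dataset.n_drugs, self._dataset.n_drugs))
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, dataset: EventDataset) -> "DDIEventClassifier":
        """Rebuild a fitted classifier from a checkpoint and its dataset."""
        import json

        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["meta"]))
            arrays = {k: zf[k] for k in zf.files if k != "meta"}
        if meta["n_drugs"] != dataset.n_drugs or meta["n_events"] != dataset.n_events:
            raise ValueError("checkpoint does not match this dataset")
        clf = cls(**meta["estimator_params"])
        clf._dataset = dataset
        if clf.mode != "ablate_d":
            clf._graphs = [d.graph() for d in dataset.drugs]
            comp = compress_similarities(dataset, clf.pca_dim)
            clf._bind_feat = np.concatenate([comp[c] for c in comp], axis=1)
        clf.n_events_ = dataset.n_events
        clf.classes_ = np.arange(dataset.n_events)
        clf.stack_tags_ = list(meta["stack_tags"])
        clf._event_mats = list(arrays["event_mats"])
        clf.params_ = clf._init_params(np.random.default_rng(clf.random_state),
                                       dataset.n_drugs, dataset.n_events,
                                       len(clf.stack_tags_))
        for k, p in enumerate(clf._all_params()):
            saved = arrays[f"param_{k}"]
            if saved.shape != p.data.shape:
                raise ValueError("checkpoint parameter shapes do not match")
            p.data = saved.astype(np.float64)
        if clf.mode != "ablate_f":
            clf.selection_weights_ = clf.params_["metapath"].selection_weights()
        return clf


def cross_validate(estimator: DDIEventClassifier, dataset: EventDataset,
                   verbose: bool = False):
    """k-fold cross-validation over the dataset's assigned folds.

    Each fold's model is trained on the other folds' triples (the event
    subgraphs are rebuilt inside ``fit`` from those triples only) and scored
    on its held-out triples.  Returns (mean report, list of fitted models).
    """
    if dataset.fold_of_triple is None:
        raise ValueError("assign folds before cross-validation")
    reports, models = [], []
    for fold in sorted(set(dataset.fold_of_triple.tolist())):
        model = clone(estimator)
        model.fit(dataset, dataset.train_triples(fold))
        test = dataset.test_triples(fold)
        probs = model.predict_proba([(i, j) for i, j, _ in test])
        rep = evaluate(probs, [e for _, _, e in test])
        reports.append(rep)
        models.append(model)
        if verbose:
            print(f"fold {fold}: acc={rep.acc:.4f} f1={rep.f1:.4f} "
                  f"auc={rep.auc:.4f} aupr={rep.aupr:.4f}")
    return MetricsReport.mean_of(reports), models
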
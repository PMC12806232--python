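"""Adaptive meta-path subgraph learning and multi-channel graph convolution.

The candidate relations live in an adjacency stack: one 0/1 subgraph per DDI
event type, two feature-similarity graphs (structure and bind-protein), and
the identity matrix (so short meta-paths remain expressible).  A meta-path of
length L corresponds to the product A_{t1}...A_{tL} of per-relation adjacency
matrices; instead of picking the t's discretely, each factor is a softmax-
weighted convex combination of the whole stack (soft selection), which lets
gradient descent choose the relations.  After every product the running
matrix is row-normalized by its degree matrix, D^-1 A_i A_j, for numerical
stability; row normalization telescopes, so the result equals normalizing the
raw product once.

C independent channels each learn their own subgraph; a shared-weight graph
convolution sigma(D^-1 A_l X W) runs on every channel and the channel outputs
are concatenated column-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .data import AdjacencyStack


def _stack_matrices(stack):
    if isinstance(stack, AdjacencyStack):
        return stack.matrices
    return list(stack)


@dataclass
class SimilarityGraphParams:
    """K-head weighted-cosine similarity graph: weights W (K, d), threshold eps."""

    W: Tensor  # (K, d) element-wise head weights
    epsilon: float

    @classmethod
    def init(cls, rng: np.random.Generator, dim: int, n_heads: int = 2,
             epsilon: float = 0.5) -> "SimilarityGraphParams":
        if n_heads < 1:
            raise ValueError("need at least one cosine head")
        if not 0.0 <= epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        # init near 1 so the initial graph is close to plain cosine similarity
        return cls(W=Tensor(1.0 + 0.01 * rng.standard_normal((n_heads, dim)),
                            requires_grad=True),
                   epsilon=epsilon)

    def parameters(self) -> list:
        return [self.W]


def feature_similarity_graph(embeddings, params: SimilarityGraphParams) -> Tensor:
    """Thresholded mean weighted-cosine similarity graph.

    S[i,j] = mean_k cos(W_k * E_i, W_k * E_j) where it reaches the threshold
    ``epsilon``, else 0; the diagonal is forced to 0 (self-connectivity comes
    only from the identity matrix in the stack); all-zero rows get cosine 0.
    """
    E = as_tensor(embeddings)
    n = E.shape[0]
    K = params.W.shape[0]
    S = None
    for k in range(K):
        Z = E * params.W[k]
        norms = (Z * Z).sum(axis=1, keepdims=True).sqrt()
        denom = norms + (norms.data == 0.0).astype(float)  # zero rows -> cos 0
        Zn = Z / denom
        C = Zn @ Zn.T
        S = C if S is None else S + C
    S = S * (1.0 / K)
    mask = (S.data >= params.epsilon) & ~np.eye(n, dtype=bool)
    return S * mask.astype(float)


def soft_select(stack, logits) -> Tensor:
    """Softmax-weighted convex combination of the adjacency stack."""
    mats = _stack_matrices(stack)
    logits = as_tensor(logits)
    if logits.shape[0] != len(mats):
        raise ValueError("logit count must equal stack size")
    w = logits.softmax(axis=0)
    out = w[0] * as_tensor(mats[0])
    for t in range(1, len(mats)):
        out = out + w[t] * as_tensor(mats[t])
    return out


def row_normalize(A) -> Tensor:
    """D^-1 A with D = diag(row sums); zero rows pass through as zero rows."""
    A = as_tensor(A)
    rs = A.sum(axis=1, keepdims=True)
    denom = rs + (rs.data == 0.0).astype(float)
    return A / denom


def metapath_layer(A_prev, stack, logits) -> Tensor:
    """Multiply the running meta-path matrix by one soft-selected factor.

    P = A_prev @ soft_select(stack, logits); returns D^-1 P (degree-matrix
    normalization), leaving zero-degree rows as zero rows.
    """
    A_prev = as_tensor(A_prev)
    sel = soft_select(stack, logits)
    if A_prev.shape[1] != sel.shape[0]:
        raise ValueError("adjacency dimension mismatch")
    return row_normalize(A_prev @ sel)


@dataclass
class MetaPathParams:
    """Per-channel, per-factor selection logits and the shared GCN weight."""

    logits: Tensor  # (C, L, stack_size)
    W_gcn: Tensor  # (out_dim, d_x)

    @classmethod
    def init(cls, rng: np.random.Generator, stack_size: int, n_channels: int,
             n_layers: int, d_x: int, out_dim: int,
             identity_slot: int | None = None) -> "MetaPathParams":
        """``identity_slot`` biases that stack member's initial selection
        weight (+4 logits, ~0.9 softmax weight over a 6-member stack), so
        channels start close to plain feature propagation and drift onto
        relations only as they prove useful."""
        if n_layers < 1:
            raise ValueError("need at least one layer")
        s = np.sqrt(6.0 / (d_x + out_dim))
        logits = 0.01 * rng.standard_normal((n_channels, n_layers, stack_size))
        if identity_slot is not None:
            logits[:, :, identity_slot] += 4.0
        return cls(
            logits=Tensor(logits, requires_grad=True),
            W_gcn=Tensor(rng.uniform(-s, s, size=(out_dim, d_x)), requires_grad=True),
        )

    @property
    def n_channels(self) -> int:
        return self.logits.shape[0]

    @property
    def n_layers(self) -> int:
        return self.logits.shape[1]

    def selection_weights(self) -> np.ndarray:
        """Softmax selection weights, shape (C, L, stack_size)."""
        z = self.logits.data - self.logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def parameters(self) -> list:
        return [self.logits, self.W_gcn]


def metapath_subgraphs(stack, params: MetaPathParams) -> list:
    """The learned normalized subgraph of every channel (list of Tensors)."""
    n = _stack_matrices(stack)[0].shape[0]
    eye = np.eye(n)
    subgraphs = []
    for c in range(params.n_channels):
        A = as_tensor(eye)
        for l in range(params.n_layers):
            A = metapath_layer(A, stack, params.logits[c, l])
        subgraphs.append(A)
    return subgraphs


def gcn_fuse(channel_subgraphs: list, X, W, n_channels: int | None = None) -> Tensor:
    """Shared-weight GCN per channel, ReLU, column-wise concatenation."""
    if n_channels is not None and len(channel_subgraphs) != n_channels:
        raise ValueError(
            f"expected {n_channels} channel subgraphs, got {len(channel_subgraphs)}"
        )
    X, W = as_tensor(X), as_tensor(W)
    outs = [(row_normalize(A) @ X @ W.T).relu() for A in channel_subgraphs]
    return concat(outs, axis=1)


def run_metapath_network(stack, X, params: MetaPathParams) -> Tensor:
    """Learned subgraph per channel, then fused node features E^' (N, C*out)."""
    return gcn_fuse(metapath_subgraphs(stack, params), X, params.W_gcn,
                    n_channels=params.n_channels)


def export_subgraphs_csv(path, stack, params: MetaPathParams,
                         threshold: float = 0.0) -> None:
    """Write learned subgraph edges as CSV (i, j, weight, channel)."""
    import pandas as pd

    rows = []
    for c, A in enumerate(metapath_subgraphs(stack, params)):
        ii, jj = np.nonzero(A.data > threshold)
        for i, j in zip(ii, jj):
            rows.append((i, j, A.data[i, j], c))
    pd.DataFrame(rows, columns=["i", "j", "weight", "channel"]).to_csv(
        path, index=False
    )
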
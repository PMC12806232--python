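"""Bind-protein feature encoder.

Every drug carries four binary annotation vectors — transporters, carriers,
enzymes and targets it binds.  Raw bit vectors are long and sparse, so the
per-drug feature is built indirectly:

1. per entity class, the drug-drug Jaccard similarity matrix
   J[i,j] = |x_i & x_j| / |x_i | x_j|  (0 when both vectors are empty);
2. PCA compression of each N_d x N_d similarity matrix to N_d x D;
3. the four compressed rows, concatenated, pass through an autoencoder whose
   encoder applies one single-head scaled-dot-product self-attention layer
   over the four entity-class blocks before its output layer.  The encoder
   output is the dense bind-protein embedding E_i; the mirror decoder's
   reconstruction MSE is an auxiliary training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .autodiff import Tensor, as_tensor, concat

#: concatenation order of the entity-class blocks fed to the autoencoder
BLOCK_ORDER: tuple[str, ...] = ("transporter", "carrier", "target", "enzyme")


def jaccard_matrix(bits) -> np.ndarray:
    """Pairwise Jaccard similarity of the rows of a binary matrix.

    ``J[i,j] = |x_i & x_j| / (|x_i| + |x_j| - |x_i & x_j|)``; defined as 0
    when both rows are all-zero.  Symmetric, entries in [0,1], unit diagonal
    for any nonzero row.
    """
    bits = np.asarray(bits)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("descriptor matrix must be binary")
    b = bits.astype(np.float64)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return J


def pca_compress(matrix, n_components: int) -> np.ndarray:
    """Project rows onto the top principal components of the centered matrix.

    Deterministic up to sign; the sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if n_components > matrix.shape[0]:
        raise ValueError(
            f"n_components={n_components} exceeds {matrix.shape[0]} rows"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    comps = pca.components_
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    return scores


def compress_similarities(dataset, n_components: int) -> dict:
    """Per entity class: Jaccard similarity then PCA, as N_d x D matrices."""
    return {
        cls: pca_compress(jaccard_matrix(dataset.descriptor_matrix(cls)), n_components)
        for cls in BLOCK_ORDER
    }


def _glorot(rng, fan_out, fan_in):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_out, fan_in))


@dataclass
class AutoencoderParams:
    """Encoder / self-attention / decoder weights.

    The encoder maps 4D -> hidden (ReLU), splits the hidden layer into the
    four entity-class tokens for self-attention, then maps hidden -> out_dim.
    The decoder mirrors it: out_dim -> hidden (ReLU) -> 4D.
    """

    enc_W1: Tensor
    enc_b1: Tensor
    W_q: Tensor
    W_k: Tensor
    W_v: Tensor
    enc_W2: Tensor
    enc_b2: Tensor
    dec_W1: Tensor
    dec_b1: Tensor
    dec_W2: Tensor
    dec_b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int,
             out_dim: int) -> "AutoencoderParams":
        if hidden % 4:
            raise ValueError("hidden width must be divisible by the 4 tokens")
        dtok = hidden // 4
        return cls(
            enc_W1=Tensor(_glorot(rng, hidden, in_dim), requires_grad=True),
            enc_b1=Tensor(np.zeros(hidden), requires_grad=True),
            W_q=Tensor(_glorot(rng, dtok, dtok), requires_grad=True),
            W_k=Tensor(_glorot(rng, dtok, dtok), requires_grad=True),
            W_v=Tensor(_glorot(rng, dtok, dtok), requires_grad=True),
            enc_W2=Tensor(_glorot(rng, out_dim, hidden), requires_grad=True),
            enc_b2=Tensor(np.zeros(out_dim), requires_grad=True),
            dec_W1=Tensor(_glorot(rng, hidden, out_dim), requires_grad=True),
            dec_b1=Tensor(np.zeros(hidden), requires_grad=True),
            dec_W2=Tensor(_glorot(rng, in_dim, hidden), requires_grad=True),
            dec_b2=Tensor(np.zeros(in_dim), requires_grad=True),
        )

    @property
    def token_dim(self) -> int:
        return self.W_q.shape[0]

    def parameters(self) -> list:
        return [self.enc_W1, self.enc_b1, self.W_q, self.W_k, self.W_v,
                self.enc_W2, self.enc_b2, self.dec_W1, self.dec_b1,
                self.dec_W2, self.dec_b2]


def self_attention(tokens: list, W_q: Tensor, W_k: Tensor, W_v: Tensor):
    """Single-head scaled dot-product attention over a short token list.

    ``tokens`` is a list of (N, dtok) tensors.  Returns (attended tokens,
    attention weights) where weights[a] is the (N, n_tokens) softmax row for
    query token a.
    """
    dtok = W_q.shape[0]
    Q = [t @ W_q.T for t in tokens]
    K = [t @ W_k.T for t in tokens]
    V = [t @ W_v.T for t in tokens]
    scale = 1.0 / np.sqrt(dtok)
    outs, weights = [], []
    for a in range(len(tokens)):
        scores = concat(
            [(Q[a] * K[b]).sum(axis=1, keepdims=True) * scale
             for b in range(len(tokens))],
            axis=1,
        )
        w = scores.softmax(axis=1)
        weights.append(w)
        out = w[:, 0:1] * V[0]
        for b in range(1, len(tokens)):
            out = out + w[:, b:b + 1] * V[b]
        outs.append(out)
    return outs, weights


def encode_bind_protein(features, params: AutoencoderParams,
                        return_attention: bool = False):
    """Encoder half: concatenated block features (N, 4D) -> embeddings E (N, out)."""
    x = as_tensor(features)
    a1 = (x @ params.enc_W1.T + params.enc_b1).relu()
    dtok = params.token_dim
    tokens = [a1[:, k * dtok:(k + 1) * dtok] for k in range(4)]
    attended, weights = self_attention(tokens, params.W_q, params.W_k, params.W_v)
    h = concat(attended, axis=1)
    E = h @ params.enc_W2.T + params.enc_b2
    if return_attention:
        return E, weights
    return E


def decode_bind_protein(E, params: AutoencoderParams) -> Tensor:
    E = as_tensor(E)
    d1 = (E @ params.dec_W1.T + params.dec_b1).relu()
    return d1 @ params.dec_W2.T + params.dec_b2


def autoencoder_reconstruction_loss(features, params: AutoencoderParams) -> Tensor:
    """Mean squared error between the decoder output and the raw input batch."""
    x = as_tensor(features)
    recon = decode_bind_protein(encode_bind_protein(x, params), params)
    diff = recon - x
    return (diff * diff).mean()
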
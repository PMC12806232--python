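"""Jaccard similarity, PCA compression, and the self-attention autoencoder."""

import numpy as np
import pytest

from ddievent.autodiff import Tensor
from ddievent.bind_protein import (AutoencoderParams,
                                   autoencoder_reconstruction_loss,
                                   encode_bind_protein, jaccard_matrix,
                                   pca_compress, self_attention)


def _jaccard_oracle(bits):
    sets = [set(np.flatnonzero(row)) for row in bits]
    n = len(sets)
    J = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = sets[i] | sets[j]
            J[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return J


class TestJaccard:
    def test_identical_nonzero_rows_give_one(self):
        bits = np.array([[1, 1, 0, 1], [1, 1, 0, 1]])
        np.testing.assert_array_equal(jaccard_matrix(bits),
                                      np.ones((2, 2)))

    def test_worked_example(self):
        bits = np.array([[1, 1, 0, 1], [1, 0, 0, 1]])
        assert jaccard_matrix(bits)[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_rows_give_zero(self):
        bits = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert jaccard_matrix(bits)[0, 1] == 0.0

    def test_double_zero_row_defined_as_zero(self):
        bits = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 1]])
        J = jaccard_matrix(bits)
        assert J[0, 1] == 0.0 and J[0, 0] == 0.0 and J[2, 2] == 1.0

    def test_matches_set_oracle_exactly(self, rng):
        bits = (rng.random((40, 25)) < 0.3).astype(int)
        np.testing.assert_array_equal(jaccard_matrix(bits),
                                      _jaccard_oracle(bits))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            jaccard_matrix(np.array([[0, 2], [1, 0]]))


class TestPCA:
    def test_rank_one_matrix_is_exact_with_single_component(self, rng):
        u, v = rng.standard_normal(6), rng.standard_normal(6)
        M = np.outer(u, v)  # column-centered M has rank 1
        scores = pca_compress(M, 1)
        centered = M - M.mean(axis=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(scores), pdist(centered), atol=1e-8)

    def test_full_components_preserve_centered_variance(self, rng):
        M = rng.standard_normal((6, 6))
        scores = pca_compress(M, 6)
        centered = M - M.mean(axis=0)
        assert np.var(scores) == pytest.approx(np.var(centered), rel=1e-10)

    def test_matches_eigh_oracle_up_to_sign_convention(self, rng):
        M = rng.standard_normal((6, 6))
        M = (M + M.T) / 2
        scores = pca_compress(M, 3)
        centered = M - M.mean(axis=0)
        cov = centered.T @ centered / (6 - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:3]
        comps = vecs[:, order].T
        for k in range(3):
            j = np.argmax(np.abs(comps[k]))
            if comps[k, j] < 0:
                comps[k] = -comps[k]
        np.testing.assert_allclose(scores, centered @ comps.T, atol=1e-8)

    def test_pairwise_distances_preserved_at_full_rank(self, rng):
        M = rng.standard_normal((5, 5))
        scores = pca_compress(M, 5)
        centered = M - M.mean(axis=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(scores), pdist(centered), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_compress(rng.standard_normal((4, 4)), 5)


class TestAutoencoder:
    @pytest.fixture
    def params(self, rng):
        return AutoencoderParams.init(rng, in_dim=16, hidden=8, out_dim=5)

    def test_identical_tokens_get_uniform_attention(self, rng, params):
        tok = Tensor(rng.standard_normal((3, params.token_dim)))
        _, weights = self_attention([tok] * 4, params.W_q, params.W_k, params.W_v)
        for w in weights:
            np.testing.assert_allclose(w.data, 0.25, atol=1e-12)

    def test_zero_parameters_give_zero_embedding(self, rng, params):
        for t in params.parameters():
            t.data[...] = 0.0
        E = encode_bind_protein(rng.standard_normal((3, 16)), params)
        np.testing.assert_allclose(E.data, 0.0)

    def test_forward_matches_manual_transcription(self, rng, params):
        from scipy.special import expit  # noqa: F401  (symmetry with other tests)
        x = rng.standard_normal((2, 16))
        a1 = np.maximum(x @ params.enc_W1.data.T + params.enc_b1.data, 0)
        d = params.token_dim
        toks = [a1[:, k * d:(k + 1) * d] for k in range(4)]
        Q = [t @ params.W_q.data.T for t in toks]
        K = [t @ params.W_k.data.T for t in toks]
        V = [t @ params.W_v.data.T for t in toks]
        outs = []
        for a in range(4):
            scores = np.stack([(Q[a] * K[b]).sum(axis=1) for b in range(4)],
                              axis=1) / np.sqrt(d)
            w = np.exp(scores - scores.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            outs.append(sum(w[:, b:b + 1] * V[b] for b in range(4)))
        h = np.concatenate(outs, axis=1)
        expect = h @ params.enc_W2.data.T + params.enc_b2.data
        got = encode_bind_protein(x, params).data
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_encoding_is_deterministic(self, rng, params):
        x = rng.standard_normal((3, 16))
        a = encode_bind_protein(x, params).data
        b = encode_bind_protein(x, params).data
        np.testing.assert_array_equal(a, b)

    def test_zero_parameter_loss_is_mean_square_input(self, rng, params):
        for t in params.parameters():
            t.data[...] = 0.0
        x = rng.standard_normal((3, 16))
        loss = autoencoder_reconstruction_loss(x, params)
        assert float(loss.data) == pytest.approx(np.mean(x ** 2))

    def test_loss_matches_direct_mse(self, rng, params):
        from ddievent.bind_protein import decode_bind_protein
        x = rng.standard_normal((4, 16))
        recon = decode_bind_protein(encode_bind_protein(x, params), params).data
        assert float(autoencoder_reconstruction_loss(x, params).data) == \
            pytest.approx(np.mean((recon - x) ** 2))

    def test_hidden_width_must_split_into_four_tokens(self, rng):
        with pytest.raises(ValueError):
            AutoencoderParams.init(rng, in_dim=16, hidden=10, out_dim=5)
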
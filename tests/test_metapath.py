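"""Similarity graphs, soft relation selection, meta-path products, GCN fusion."""

import numpy as np
import pytest

from ddievent.autodiff import Adam, Tensor
from ddievent.metapath import (MetaPathParams, SimilarityGraphParams,
                               feature_similarity_graph, gcn_fuse,
                               metapath_layer, metapath_subgraphs,
                               row_normalize, run_metapath_network,
                               soft_select)


def _sim_params(rng, dim, n_heads=2, epsilon=0.5, weights=None):
    p = SimilarityGraphParams.init(rng, dim, n_heads, epsilon)
    if weights is not None:
        p.W.data[...] = weights
    return p


class TestSimilarityGraph:
    def test_identical_vectors_reach_cosine_one(self, rng):
        E = np.tile(rng.standard_normal(5), (2, 1))
        S = feature_similarity_graph(E, _sim_params(rng, 5, epsilon=0.9))
        assert S.data[0, 1] == pytest.approx(1.0)
        assert S.data[0, 0] == 0.0  # diagonal forced off

    def test_orthogonal_vectors_are_thresholded_away(self, rng):
        E = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = _sim_params(rng, 2, epsilon=0.5, weights=np.ones((2, 2)))
        S = feature_similarity_graph(E, p)
        assert S.data[0, 1] == 0.0

    def test_matches_per_head_cosine_oracle(self, rng):
        E = rng.standard_normal((4, 3))
        p = _sim_params(rng, 3, n_heads=2, epsilon=0.0)
        S = feature_similarity_graph(E, p).data
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                acc = 0.0
                for k in range(2):
                    a = p.W.data[k] * E[i]
                    b = p.W.data[k] * E[j]
                    acc += a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                expect = acc / 2 if acc / 2 >= p.epsilon else 0.0
                assert S[i, j] == pytest.approx(expect, abs=1e-10)

    def test_zero_embedding_row_gets_zero_cosine(self, rng):
        E = np.array([[0.0, 0.0], [1.0, 1.0]])
        S = feature_similarity_graph(E, _sim_params(rng, 2, epsilon=0.0))
        assert S.data[0, 1] == 0.0


class TestSoftSelect:
    def test_saturated_logits_return_selected_matrix(self, rng):
        mats = [rng.random((3, 3)) for _ in range(3)]
        out = soft_select(mats, np.array([0.0, 2000.0, 0.0]))
        np.testing.assert_allclose(out.data, mats[1], atol=1e-9)

    def test_equal_logits_give_elementwise_mean(self, rng):
        mats = [rng.random((3, 3)) for _ in range(2)]
        out = soft_select(mats, np.zeros(2))
        np.testing.assert_allclose(out.data, (mats[0] + mats[1]) / 2, atol=1e-12)

    def test_matches_weighted_sum_oracle(self, rng):
        mats = [rng.random((4, 4)) for _ in range(3)]
        logits = np.array([1.0, 2.0, 3.0])
        w = np.exp(logits) / np.exp(logits).sum()
        out = soft_select(mats, logits)
        np.testing.assert_allclose(out.data, sum(wk * m for wk, m in zip(w, mats)),
                                   atol=1e-12)

    def test_convexity_bounds_entries(self, rng):
        mats = [rng.random((4, 4)) for _ in range(3)]
        out = soft_select(mats, rng.standard_normal(3)).data
        lo = np.minimum.reduce(mats)
        hi = np.maximum.reduce(mats)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_logit_count_must_match_stack(self, rng):
        with pytest.raises(ValueError):
            soft_select([np.eye(2)], np.zeros(2))


class TestMetaPathLayer:
    def test_identity_prev_yields_row_normalized_selection(self, rng):
        A = (rng.random((4, 4)) < 0.5).astype(float)
        out = metapath_layer(np.eye(4), [A], np.zeros(1)).data
        rs = A.sum(axis=1, keepdims=True)
        expect = np.divide(A, rs, out=np.zeros_like(A), where=rs > 0)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_one_hot_product_matches_dense_oracle(self, rng):
        A1 = (rng.random((4, 4)) < 0.6).astype(float)
        A2 = (rng.random((4, 4)) < 0.6).astype(float)
        stack = [A1, A2, np.eye(4)]
        step1 = metapath_layer(np.eye(4), stack, np.array([2000.0, 0, 0]))
        step2 = metapath_layer(step1, stack, np.array([0, 2000.0, 0])).data
        P = A1 @ A2
        rs = P.sum(axis=1, keepdims=True)
        expect = np.divide(P, rs, out=np.zeros_like(P), where=rs > 0)
        np.testing.assert_allclose(step2, expect, atol=1e-9)

    def test_two_hop_reachability_appears(self):
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        stack = [path]
        out = metapath_layer(metapath_layer(np.eye(3), stack, np.zeros(1)),
                             stack, np.zeros(1)).data
        assert out[0, 2] > 0  # 0-1-2 two-hop path

    def test_nonzero_rows_are_stochastic_and_zero_rows_stay(self, rng):
        A = rng.random((5, 5))
        A[2] = 0.0
        out = row_normalize(A).data
        np.testing.assert_allclose(out[[0, 1, 3, 4]].sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(out[2], np.zeros(5))


class TestFusion:
    def test_identity_subgraph_reduces_to_dense_layer(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((2, 3))
        out = gcn_fuse([Tensor(np.eye(4))], X, W).data
        np.testing.assert_allclose(out, np.maximum(X @ W.T, 0), atol=1e-12)

    def test_zero_features_give_zero_output(self, rng):
        out = gcn_fuse([Tensor(np.eye(3))], np.zeros((3, 2)),
                       rng.standard_normal((2, 2))).data
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_two_channels_match_loop_oracle_and_concatenate(self, rng):
        X = rng.standard_normal((3, 4))
        W = rng.standard_normal((2, 4))
        A1 = (rng.random((3, 3)) < 0.7).astype(float)
        A2 = (rng.random((3, 3)) < 0.7).astype(float)
        out = gcn_fuse([Tensor(A1), Tensor(A2)], X, W).data
        pieces = []
        for A in (A1, A2):
            rs = A.sum(axis=1, keepdims=True)
            An = np.divide(A, rs, out=np.zeros_like(A), where=rs > 0)
            pieces.append(np.maximum(An @ X @ W.T, 0))
        np.testing.assert_allclose(out, np.concatenate(pieces, axis=1),
                                   atol=1e-12)

    def test_channel_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gcn_fuse([Tensor(np.eye(2))], np.zeros((2, 2)),
                     np.zeros((2, 2)), n_channels=3)


class TestNetwork:
    def test_identity_only_stack_reduces_to_dense_layer(self, rng):
        X = rng.standard_normal((4, 3))
        params = MetaPathParams.init(rng, 1, n_channels=2, n_layers=1,
                                     d_x=3, out_dim=2)
        out = run_metapath_network([np.eye(4)], X, params).data
        per = np.maximum(X @ params.W_gcn.data.T, 0)
        np.testing.assert_allclose(out, np.concatenate([per, per], axis=1),
                                   atol=1e-12)

    def test_output_width_is_channels_times_dim(self, rng):
        stack = [(rng.random((5, 5)) < 0.5).astype(float) for _ in range(3)]
        params = MetaPathParams.init(rng, 3, n_channels=3, n_layers=2,
                                     d_x=4, out_dim=6)
        out = run_metapath_network(stack, rng.standard_normal((5, 4)), params)
        assert out.shape == (5, 3 * 6)

    def test_one_hot_sequences_match_normalized_product_oracle(self, rng):
        stack = [(rng.random((6, 6)) < 0.5).astype(float) for _ in range(4)]
        params = MetaPathParams.init(rng, 4, n_channels=1, n_layers=2,
                                     d_x=2, out_dim=2)
        for t1 in range(4):
            for t2 in range(4):
                params.logits.data[...] = 0.0
                params.logits.data[0, 0, t1] = 2000.0
                params.logits.data[0, 1, t2] = 2000.0
                sub = metapath_subgraphs(stack, params)[0].data
                P = stack[t1] @ stack[t2]
                rs = P.sum(axis=1, keepdims=True)
                expect = np.divide(P, rs, out=np.zeros_like(P), where=rs > 0)
                np.testing.assert_allclose(sub, expect, atol=1e-9)

    def test_selection_logits_receive_gradient(self, rng):
        stack = [(rng.random((4, 4)) < 0.5).astype(float), np.eye(4)]
        params = MetaPathParams.init(rng, 2, n_channels=1, n_layers=2,
                                     d_x=3, out_dim=2)
        out = run_metapath_network(stack, rng.standard_normal((4, 3)), params)
        (out * out).sum().backward()
        assert params.logits.grad is not None
        assert np.abs(params.logits.grad).sum() > 0
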
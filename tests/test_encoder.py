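"""Encoder vs scalar brute-force oracles: attention, fusion, average view."""

import numpy as np
import pytest

from metaddi import nn
from metaddi.encoder import (AVERAGE_VIEW, average_adjacency, encode_average_view,
                             gat_encode, init_encoder_params, semantic_fuse,
                             transform_features)
from metaddi.metapath import SubGraphSet


def scalar_gat_oracle(adj, h, gp, leaky=0.2):
    """Direct per-node evaluation of the attention equations."""
    n, d = h.shape
    n_heads = len(gp.a)
    dh = d // n_heads
    A = adj.copy().astype(float)
    np.fill_diagonal(A, 1.0)  # self-loops
    z = np.zeros((n, d))
    slope = float(gp.prelu_slope.data)
    for k in range(n_heads):
        a = gp.a[k].data
        W = gp.W[k].data
        for i in range(n):
            nbrs = [j for j in range(n) if A[i, j] > 0]
            e = []
            for j in nbrs:
                pre = a @ np.concatenate([h[i], h[j]])
                e.append(pre if pre > 0 else leaky * pre)
            e = np.array(e)
            alpha = np.exp(e - e.max())
            alpha /= alpha.sum()
            agg = sum(alpha[t] * (W @ h[j]) for t, j in enumerate(nbrs)) + gp.b.data
            z[i, k * dh:(k + 1) * dh] = np.where(agg > 0, agg, slope * agg)
    return z


def scalar_semantic_oracle(z_list, W1, b1, q1):
    scores = []
    for z in z_list:
        s = np.mean([np.tanh(W1 @ zi + b1) for zi in z], axis=0)
        scores.append(q1 @ s)
    scores = np.array(scores)
    beta = np.exp(scores - scores.max())
    beta /= beta.sum()
    z_f = sum(b * z for b, z in zip(beta, z_list))
    return beta, z_f


@pytest.fixture
def setup():
    rng = np.random.default_rng(42)
    params = init_encoder_params(rng, n_features=5, d=8, n_heads=2,
                                 graph_names=["DCD", "DPD"])
    X = rng.random((4, 5))
    adj = np.array([[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]])
    return rng, params, X, adj


class TestTransformFeatures:
    def test_zero_params_give_zero_embeddings(self, setup):
        _, params, X, _ = setup
        params.W.data[:] = 0
        params.b.data[:] = 0
        h = transform_features(X, params)
        assert not h.data.any()  # ELU(0) = 0

    def test_identical_rows_map_identically(self, setup):
        _, params, X, _ = setup
        X2 = np.vstack([X[0], X[0]])
        h = transform_features(X2, params)
        assert np.allclose(h.data[0], h.data[1])

    def test_matches_scalar_arithmetic(self, setup):
        _, params, X, _ = setup
        h = transform_features(X, params)
        pre = params.W.data @ X[1] + params.b.data
        expect = np.where(pre > 0, pre, np.exp(pre) - 1)
        assert np.allclose(h.data[1], expect, atol=1e-12)

    def test_rejects_non_finite_input(self, setup):
        _, params, X, _ = setup
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            transform_features(X, params)


class TestGatEncode:
    def test_matches_scalar_oracle(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        z = gat_encode(adj, h, params.graph_params["DCD"])
        expect = scalar_gat_oracle(adj, h.data, params.graph_params["DCD"])
        assert np.allclose(z.data, expect, atol=1e-6)

    def test_attention_rows_sum_to_one(self, setup):
        _, params, X, adj = setup
        h = transform_features(X, params)
        _, att = gat_encode(adj, h, params.graph_params["DCD"], return_attention=True)
        mask = adj + np.eye(4)
        for alpha in att:
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
            assert not (alpha * (mask == 0)).any()  # no weight off-support

    def test_single_neighbor_gets_unit_attention(self, setup):
        _, params, X, _ = setup
        h = transform_features(X, params)
        lone = np.zeros((4, 4), dtype=int)
        lone[0, 1] = lone[1, 0] = 1
        _, att = gat_encode(lone, h, params.graph_params["DCD"], return_attention=True)
        # drug 3 only has its self-loop
        for alpha in att:
            assert alpha[3, 3] == pytest.approx(1.0)

    def test_isolated_nodes_still_embedded(self, setup):
        _, params, X, _ = setup
        h = transform_features(X, params)
        z = gat_encode(np.zeros((4, 4), dtype=int), h, params.graph_params["DCD"])
        assert np.isfinite(z.data).all()

    def test_gradient_reaches_every_attention_parameter(self, setup):
        _, params, X, adj = setup
        gp = params.graph_params["DCD"]

        def loss():
            h = transform_features(X, params)
            return (gat_encode(adj, h, gp) ** 2).sum()

        assert nn.grad_check(loss, gp.tensors() + [params.W, params.b],
                             rtol=1e-3, atol=1e-6)

    def test_self_aggregation_switch_uses_own_embedding(self, setup):
        _, params, X, adj = setup
        h = transform_features(X, params)
        z = gat_encode(adj, h, params.graph_params["DCD"], self_aggregate=True)
        # attention weights sum to 1, so aggregation reduces to PReLU(W h_i + b)
        gp = params.graph_params["DCD"]
        dh = 4
        pre = h.data @ gp.W[0].data.T + gp.b.data
        expect = np.where(pre > 0, pre, float(gp.prelu_slope.data) * pre)
        assert np.allclose(z.data[:, :dh], expect, atol=1e-9)


class TestSemanticFuse:
    def test_single_graph_passthrough(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        z = gat_encode(adj, h, params.graph_params["DCD"])
        beta, z_f = semantic_fuse([z], params)
        assert beta.data == pytest.approx([1.0])
        assert np.allclose(z_f.data, z.data)

    def test_identical_embeddings_uniform_weights(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        z = gat_encode(adj, h, params.graph_params["DCD"])
        beta, _ = semantic_fuse([z, z, z], params)
        assert np.allclose(beta.data, 1 / 3)

    def test_matches_scalar_oracle(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        z1 = gat_encode(adj, h, params.graph_params["DCD"])
        z2 = gat_encode(adj, h, params.graph_params["DPD"])
        beta, z_f = semantic_fuse([z1, z2], params)
        eb, ez = scalar_semantic_oracle([z1.data, z2.data], params.W1.data,
                                        params.b1.data, params.q1.data)
        assert np.allclose(beta.data, eb, atol=1e-6)
        assert np.allclose(z_f.data, ez, atol=1e-6)

    def test_permutation_equivariance(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        z1 = gat_encode(adj, h, params.graph_params["DCD"])
        z2 = gat_encode(adj, h, params.graph_params["DPD"])
        b12, f12 = semantic_fuse([z1, z2], params)
        b21, f21 = semantic_fuse([z2, z1], params)
        assert np.allclose(b12.data, b21.data[::-1])
        assert np.allclose(f12.data, f21.data)

    def test_dropping_a_graph_renormalizes(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        zs = [gat_encode(adj, h, params.graph_params[n]) for n in ("DCD", "DPD")]
        beta_full, _ = semantic_fuse(zs, params)
        beta_drop, _ = semantic_fuse(zs[:1], params)
        assert beta_drop.data.sum() == pytest.approx(1.0)

    def test_empty_list_rejected(self, setup):
        _, params, _, _ = setup
        with pytest.raises(ValueError):
            semantic_fuse([], params)


class TestAverageView:
    def test_average_of_single_graph_is_itself(self, setup):
        _, _, _, adj = setup
        sgs = SubGraphSet([adj], ["DCD"], [1])
        assert np.array_equal(average_adjacency(sgs), adj.astype(float))

    def test_fractional_entries(self):
        g1 = np.array([[0, 1], [1, 0]])
        g0 = np.zeros((2, 2), dtype=int)
        sgs = SubGraphSet([g1, g1, g0, g0, g0], list("abcde"), [1] * 5)
        m = average_adjacency(sgs)
        assert m[0, 1] == pytest.approx(0.4)
        assert (m >= 0).all() and (m <= 1).all()

    def test_encodes_on_support(self, setup):
        rng, params, X, adj = setup
        h = transform_features(X, params)
        sgs = SubGraphSet([adj, np.zeros_like(adj)], ["DCD", "DPD"], [1, 1])
        z = encode_average_view(sgs, h, params)
        expect = scalar_gat_oracle(adj, h.data, params.graph_params[AVERAGE_VIEW])
        assert np.allclose(z.data, expect, atol=1e-6)
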
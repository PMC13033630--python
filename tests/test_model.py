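"""Forward-pass components against independently coded nested-loop oracles."""

import math

import numpy as np
import pytest

from csgnn.graph import build_neighborhoods
from csgnn.model import (ModelParams, attention_coefficients, classify,
                         context_aggregate, decode, forward, init_params,
                         layer_forward, pair_descriptor)


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    adj = np.triu((rng.random((n, n)) < p).astype(int), 1)
    return build_neighborhoods(adj + adj.T)


def oracle_attention(features, W, q, neighborhoods, slope):
    """Explicit exp/sum softmax of LeakyReLU(q^T [Wh_i || Wh_j])."""
    out = {}
    for i, js in neighborhoods.items():
        if not js:
            continue
        scores = []
        for j in js:
            z = q @ np.concatenate([W @ features[i], W @ features[j]])
            scores.append(z if z > 0 else slope * z)
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        total = sum(exps)
        for j, e in zip(js, exps):
            out[(i, j)] = e / total
    return out


class TestAttentionCoefficients:
    def test_identical_neighbors_get_uniform_weights(self):
        feats = np.ones((4, 3))
        W = np.random.default_rng(0).normal(size=(2, 3))
        q = np.random.default_rng(1).normal(size=4)
        coeffs = attention_coefficients(feats, W, q, {0: [1, 2, 3]})
        for j in (1, 2, 3):
            assert coeffs[(0, j)] == pytest.approx(1 / 3)

    def test_single_neighbor_gets_unit_weight(self):
        feats = np.random.default_rng(2).normal(size=(3, 4))
        W = np.random.default_rng(3).normal(size=(2, 4))
        q = np.random.default_rng(4).normal(size=4)
        coeffs = attention_coefficients(feats, W, q, {1: [2]})
        assert coeffs[(1, 2)] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exp_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        feats = rng.normal(size=(6, 5))
        W = rng.normal(size=(3, 5))
        q = rng.normal(size=6)
        nbhd = {i: sorted(rng.choice(6, size=rng.integers(0, 5), replace=False).tolist())
                for i in range(6)}
        got = attention_coefficients(feats, W, q, nbhd, leaky_slope=0.2)
        expected = oracle_attention(feats, W, q, nbhd, 0.2)
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(10)
        feats = rng.normal(size=(8, 4))
        W = rng.normal(size=(3, 4))
        q = rng.normal(size=6)
        nbhd = {i: [j for j in range(8) if j != i and (i + j) % 3 == 0] for i in range(8)}
        coeffs = attention_coefficients(feats, W, q, nbhd)
        for i, js in nbhd.items():
            if js:
                assert sum(coeffs[(i, j)] for j in js) == pytest.approx(1.0, abs=1e-6)


class TestLayerForward:
    def test_isolated_node_outputs_zeros(self):
        g = build_neighborhoods(np.zeros((3, 3), dtype=int))
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(3, 4))
        h1, h2, h_cat, _ = layer_forward(feats, rng.normal(size=(2, 4)),
                                         rng.normal(size=4), rng.normal(size=4), g)
        np.testing.assert_array_equal(np.asarray(h_cat), np.zeros((3, 4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_message_passing_loop_oracle(self, seed):
        g = random_graph(8, 0.35, seed)
        rng = np.random.default_rng(100 + seed)
        d, m = 3, 5
        feats = rng.normal(size=(8, m))
        W = rng.normal(size=(d, m))
        q1, q2 = rng.normal(size=2 * d), rng.normal(size=2 * d)
        out1, out2, h_cat, _ = layer_forward(feats, W, q1, q2, g, leaky_slope=0.2)
        for order, (q, nbhd, out) in enumerate([(q1, g.n1, out1), (q2, g.n2, out2)]):
            alpha = oracle_attention(feats, W, q, nbhd, 0.2)
            for i in range(8):
                agg = np.zeros(d)
                for j in nbhd[i]:
                    agg += alpha[(i, j)] * (W @ feats[j])
                np.testing.assert_allclose(np.asarray(out)[i], np.maximum(agg, 0),
                                           atol=1e-10)


class TestPairDescriptor:
    def test_zero_inputs_give_zero_descriptor(self):
        np.testing.assert_array_equal(pair_descriptor(np.zeros(4), np.zeros(4)),
                                      np.zeros(16))

    def test_direct_arithmetic(self):
        got = pair_descriptor([1.0, 2.0], [3.0, 4.0])
        np.testing.assert_array_equal(got, [4, 6, 3, 8, 1, 2, 3, 4])

    def test_ordered_asymmetry(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert not np.array_equal(pair_descriptor(a, b), pair_descriptor(b, a))

    def test_length_is_four_times_input(self):
        rng = np.random.default_rng(0)
        for d2 in (2, 4, 8):
            assert pair_descriptor(rng.normal(size=d2), rng.normal(size=d2)).size == 4 * d2


class TestContextAggregate:
    def _setup(self, n, seed, p=0.3):
        g = random_graph(n, p, seed)
        rng = np.random.default_rng(seed + 50)
        h = rng.normal(size=(n, 4))
        # synthetic second-layer coefficient matrices: positive on masks, row-normalized
        m1, m2, _ = g.masks()
        b1 = rng.random((n, n)) * m1
        b2 = rng.random((n, n)) * m2
        s1 = b1.sum(1, keepdims=True)
        s2 = b2.sum(1, keepdims=True)
        b1 = b1 / np.where(s1 > 0, s1, 1.0)
        b2 = b2 / np.where(s2 > 0, s2, 1.0)
        return g, h, b1, b2

    def test_single_context_node_gets_unit_weight(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        g = build_neighborhoods(adj)
        h = np.arange(12.0).reshape(3, 4)
        b1 = np.zeros((3, 3))
        b1[0, 1] = b1[1, 0] = 1.0
        h_bar, w = context_aggregate(h, g, b1, np.zeros((3, 3)))
        assert w[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(h_bar[0], pair_descriptor(h[0], h[1]))
        np.testing.assert_array_equal(h_bar[2], np.zeros(16))  # empty context

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_sum_loop_oracle(self, seed):
        g, h, b1, b2 = self._setup(7, seed)
        h_bar, w = context_aggregate(h, g, b1, b2)
        for i in range(7):
            c = sorted(set(g.n1[i]) | set(g.n2[i]))
            raw = {}
            for j in c:
                in1, in2 = j in g.n1[i], j in g.n2[i]
                if in1 and in2:
                    raw[j] = 0.5 * (b1[i, j] + b2[i, j])
                elif in1:
                    raw[j] = b1[i, j]
                else:
                    raw[j] = b2[i, j]
            total = sum(raw.values())
            expected = np.zeros(16)
            for j in c:
                expected += raw[j] / total * pair_descriptor(h[i], h[j])
            if c:
                np.testing.assert_allclose(h_bar[i], expected, atol=1e-10)
                assert w[i].sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_weights_give_plain_mean(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[0, 2] = adj[2, 0] = 1
        g = build_neighborhoods(adj)
        h = np.random.default_rng(0).normal(size=(4, 2))
        b1 = np.zeros((4, 4))
        b1[0, [1, 2]] = 0.5
        h_bar, _ = context_aggregate(h, g, b1, np.zeros((4, 4)))
        expected = 0.5 * (pair_descriptor(h[0], h[1]) + pair_descriptor(h[0], h[2]))
        np.testing.assert_allclose(h_bar[0], expected)


class TestDecode:
    def _params(self, d=2, d_h=3, seed=0):
        return init_params(4, d=d, d_h=d_h, rng=seed)

    def test_zero_weights_give_half(self):
        p = self._params()
        p.dec_W1[:] = 0
        p.dec_b1[:] = 0
        p.dec_W2[:] = 0
        p.dec_b2 = np.zeros(())
        assert decode(np.random.default_rng(0).normal(size=16), p)[0] == pytest.approx(0.5)

    def test_monotone_in_output_bias(self):
        p = self._params()
        x = np.random.default_rng(1).normal(size=16)
        probs = []
        for b in (-5.0, 0.0, 5.0):
            p.dec_b2 = np.array(b)
            probs.append(decode(x, p)[0])
        assert probs[0] < probs[1] < probs[2]

    def test_matches_matrix_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        p = self._params(seed=5)
        x = rng.normal(size=16)
        z = np.maximum(p.dec_W1 @ x + p.dec_b1, 0)
        expected = 1 / (1 + np.exp(-(p.dec_W2 @ z + p.dec_b2)))
        assert decode(x, p)[0] == pytest.approx(expected[0], abs=1e-12)


class TestClassify:
    def test_boundary_is_inclusive(self):
        hard, _ = classify(np.array([0.5, 0.4999]), delta=0.5)
        np.testing.assert_array_equal(hard, [1, 0])

    def test_threshold_extremes(self):
        p = np.array([0.1, 0.9, 0.0])
        assert classify(p, delta=0.0)[0].sum() == 3
        assert classify(p, delta=1.0 + 1e-12)[0].sum() == 0

    def test_rank_ties_broken_by_index(self):
        _, ranking = classify(np.array([0.9, 0.9, 0.1]))
        np.testing.assert_array_equal(ranking, [0, 1, 2])


class TestFullForward:
    def _instance(self, seed=0, n=10, d=2):
        g = random_graph(n, 0.3, seed)
        rng = np.random.default_rng(seed + 1)
        feats = rng.normal(size=(n, 6))
        params = init_params(6, d=d, d_h=5, rng=seed + 2)
        return g, feats, params

    def test_end_to_end_matches_nested_loop_oracle(self):
        """Complete forward (attention layers -> pair context -> decoder)
        against the independent component oracles chained by hand."""
        g, feats, params = self._instance()
        result = forward(params, feats, g.masks())

        o11, o12, h1, _ = layer_forward(feats, params.W1, params.q1_order1,
                                        params.q1_order2, g, params.leaky_slope)
        # oracle layer 1 via loops
        a11 = oracle_attention(feats, params.W1, params.q1_order1, g.n1, params.leaky_slope)
        h1_oracle = np.zeros((10, 2))
        for i in range(10):
            for j in g.n1[i]:
                h1_oracle[i] += a11[(i, j)] * (params.W1 @ feats[j])
        np.testing.assert_allclose(np.asarray(o11), np.maximum(h1_oracle, 0), atol=1e-8)

        # layer 2 oracle on h1
        h1 = np.asarray(h1)
        b1 = oracle_attention(h1, params.W2, params.q2_order1, g.n1, params.leaky_slope)
        b2 = oracle_attention(h1, params.W2, params.q2_order2, g.n2, params.leaky_slope)
        h21 = np.zeros((10, 2))
        h22 = np.zeros((10, 2))
        for i in range(10):
            for j in g.n1[i]:
                h21[i] += b1[(i, j)] * (params.W2 @ h1[j])
            for j in g.n2[i]:
                h22[i] += b2[(i, j)] * (params.W2 @ h1[j])
        h_final = np.concatenate([np.maximum(h21, 0), np.maximum(h22, 0)], axis=1)
        np.testing.assert_allclose(np.asarray(result.h_final), h_final, atol=1e-8)

        b1_dense = np.zeros((10, 10))
        b2_dense = np.zeros((10, 10))
        for (i, j), v in b1.items():
            b1_dense[i, j] = v
        for (i, j), v in b2.items():
            b2_dense[i, j] = v
        h_bar, _ = context_aggregate(h_final, g, b1_dense, b2_dense)
        np.testing.assert_allclose(np.asarray(result.h_bar), h_bar, atol=1e-8)
        np.testing.assert_allclose(np.asarray(result.probabilities),
                                   decode(h_bar, params), atol=1e-8)

    def test_attention_rows_sum_to_one_both_layers(self):
        g, feats, params = self._instance(seed=3)
        result = forward(params, feats, g.masks())
        m1, m2, _ = g.masks()
        for attn, mask in zip(result.attention1 + result.attention2, (m1, m2, m1, m2)):
            rows = mask.any(axis=1)
            np.testing.assert_allclose(np.asarray(attn).sum(axis=1)[rows], 1.0, atol=1e-6)

    def test_forward_is_deterministic(self):
        g, feats, params = self._instance(seed=4)
        p1 = np.asarray(forward(params, feats, g.masks()).probabilities)
        p2 = np.asarray(forward(params, feats, g.masks()).probabilities)
        np.testing.assert_array_equal(p1, p2)

    def test_permutation_equivariance(self):
        g, feats, params = self._instance(seed=5)
        rng = np.random.default_rng(99)
        perm = rng.permutation(10)
        adj_p = g.adjacency[np.ix_(perm, perm)]
        g_p = build_neighborhoods(adj_p)
        p_orig = np.asarray(forward(params, feats, g.masks()).probabilities)
        p_perm = np.asarray(forward(params, feats[perm], g_p.masks()).probabilities)
        np.testing.assert_allclose(p_perm, p_orig[perm], atol=1e-10)

    def test_fully_isolated_graph_probability_from_biases_only(self):
        g = build_neighborhoods(np.zeros((4, 4), dtype=int))
        params = init_params(3, d=2, d_h=4, rng=0)
        feats = np.random.default_rng(1).normal(size=(4, 3))
        probs = np.asarray(forward(params, feats, g.masks()).probabilities)
        assert np.allclose(probs, probs[0])  # identical for every isolated node

    def test_descriptor_width_is_eight_d(self):
        for d in (1, 3):
            g, feats, _ = self._instance(seed=6)
            params = init_params(6, d=d, d_h=4, rng=7)
            result = forward(params, feats, g.masks())
            assert np.asarray(result.h_bar).shape == (10, 8 * d)


class TestCheckpointRoundTrip:
    def test_save_load_identity(self, tmp_path):
        params = init_params(5, d=3, d_h=4, rng=1)
        path = tmp_path / "ckpt.npz"
        params.save(path, config={"d": 3})
        loaded = ModelParams.load(path)
        for field in ("W1", "q1_order1", "dec_W2", "dec_b2"):
            np.testing.assert_array_equal(getattr(params, field), getattr(loaded, field))
        assert (tmp_path / "ckpt.npz.json").exists()
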
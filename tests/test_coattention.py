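"""Co-attention: affinity, attention distributions, fusion, full model.

Oracles are explicit index-loop implementations of the defining equations,
independent of the vectorized code path.
"""

import numpy as np
import pytest

import demfusion as dm
from demfusion._tensor import Tensor
from demfusion.coattention import (CoAttention, CoAttentionModel,
                                   attend_and_fuse, compute_affinity,
                                   compute_attention_distributions)


# -- explicit-loop oracle --------------------------------------------------

def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def coattention_oracle(C, S, W_l, W_s, W_c, w_hs, w_hc):
    d, N = C.shape
    _, T = S.shape
    k = W_s.shape[0]
    F = np.zeros((N, T))
    for i in range(N):
        for j in range(T):
            F[i, j] = np.tanh(C[:, i] @ W_l @ S[:, j])
    H_s = np.zeros((k, T))
    H_c = np.zeros((k, N))
    WsS, WcC = W_s @ S, W_c @ C
    for j in range(T):
        H_s[:, j] = np.tanh(WsS[:, j] + sum(WcC[:, i] * F[i, j] for i in range(N)))
    for i in range(N):
        H_c[:, i] = np.tanh(WcC[:, i] + sum(WsS[:, j] * F[i, j] for j in range(T)))
    a_s = _softmax(np.array([w_hs[:, 0] @ H_s[:, j] for j in range(T)]))
    a_c = _softmax(np.array([w_hc[:, 0] @ H_c[:, i] for i in range(N)]))
    s_hat = sum(a_s[j] * S[:, j] for j in range(T))
    c_hat = sum(a_c[i] * C[:, i] for i in range(N))
    return F, H_s, H_c, a_s, a_c, s_hat, c_hat


def _random_instance(rng, d, k, N, T):
    return (rng.normal(size=(d, N)), rng.normal(size=(d, T)),
            rng.normal(size=(d, d)), rng.normal(size=(k, d)),
            rng.normal(size=(k, d)), rng.normal(size=(k, 1)),
            rng.normal(size=(k, 1)))


class TestAffinity:
    def test_zero_weights_give_zero_affinity(self, rng):
        C, S = rng.normal(size=(3, 4)), rng.normal(size=(3, 2))
        assert np.allclose(compute_affinity(C, S, np.zeros((3, 3))), 0.0)

    def test_matches_triple_loop_on_fixed_pattern(self):
        C = np.array([[1.0, 2.0], [-1.0, 0.5]])
        S = np.array([[0.5, -2.0], [1.0, 3.0]])
        W = np.array([[1.0, -1.0], [2.0, 0.0]])
        F = compute_affinity(C, S, W)
        for i in range(2):
            for j in range(2):
                assert abs(F[i, j] - np.tanh(C[:, i] @ W @ S[:, j])) < 1e-6

    def test_entries_strictly_inside_unit_interval(self, rng):
        F = compute_affinity(rng.normal(size=(4, 6)), rng.normal(size=(4, 3)),
                             rng.normal(size=(4, 4)))
        assert np.all(np.abs(F) < 1.0)

    def test_swapping_text_columns_swaps_affinity_rows(self, rng):
        C, S, W = rng.normal(size=(3, 4)), rng.normal(size=(3, 2)), rng.normal(size=(3, 3))
        F = compute_affinity(C, S, W)
        C2 = C[:, [1, 0, 2, 3]]
        F2 = compute_affinity(C2, S, W)
        assert np.allclose(F2, F[[1, 0, 2, 3], :])

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            compute_affinity(rng.normal(size=(3, 4)), rng.normal(size=(2, 2)),
                             np.zeros((3, 3)))


class TestAttentionDistributions:
    def test_zero_maps_give_uniform_attention(self, rng):
        d, k, N, T = 3, 2, 4, 5
        C, S = rng.normal(size=(d, N)), rng.normal(size=(d, T))
        F = compute_affinity(C, S, rng.normal(size=(d, d)))
        H_s, H_c, a_s, a_c = compute_attention_distributions(
            C, S, F, np.zeros((k, d)), np.zeros((k, d)),
            rng.normal(size=(k, 1)), rng.normal(size=(k, 1)))
        assert np.allclose(H_s, 0) and np.allclose(H_c, 0)
        assert np.allclose(a_s, 1.0 / T) and np.allclose(a_c, 1.0 / N)

    def test_matches_loop_oracle_tiny_instance(self, rng):
        C, S, W_l, W_s, W_c, w_hs, w_hc = _random_instance(rng, 2, 3, 2, 2)
        F = compute_affinity(C, S, W_l)
        H_s, H_c, a_s, a_c = compute_attention_distributions(C, S, F, W_s, W_c, w_hs, w_hc)
        oF, oHs, oHc, oas, oac, _, _ = coattention_oracle(C, S, W_l, W_s, W_c, w_hs, w_hc)
        for got, want in [(F, oF), (H_s, oHs), (H_c, oHc), (a_s.ravel(), oas),
                          (a_c.ravel(), oac)]:
            assert np.allclose(got, want, atol=1e-6)

    def test_softmax_shift_invariance(self, rng):
        logits = rng.normal(size=(1, 6))
        a = Tensor(logits).softmax(-1).data
        b = Tensor(logits + 3.7).softmax(-1).data
        assert np.allclose(a, b, atol=1e-6)

    def test_distributions_normalized(self, rng):
        C, S, W_l, W_s, W_c, w_hs, w_hc = _random_instance(rng, 3, 4, 5, 6)
        F = compute_affinity(C, S, W_l)
        _, _, a_s, a_c = compute_attention_distributions(C, S, F, W_s, W_c, w_hs, w_hc)
        assert abs(a_s.sum() - 1) < 1e-6 and abs(a_c.sum() - 1) < 1e-6
        assert np.all(a_s >= 0) and np.all(a_c >= 0)


class TestAttendAndFuse:
    def test_uniform_weights_give_column_mean(self, rng):
        S = rng.normal(size=(3, 5))
        C = rng.normal(size=(3, 4))
        s_hat, c_hat, p = attend_and_fuse(C, S, np.full(5, 0.2), np.full(4, 0.25))
        assert np.allclose(s_hat.ravel(), S.mean(axis=1))
        assert p.shape == (1, 6)

    def test_one_hot_selects_column(self, rng):
        S = rng.normal(size=(3, 4))
        a_s = np.eye(4)[2]
        s_hat, _, _ = attend_and_fuse(rng.normal(size=(3, 2)), S, a_s, np.array([0.5, 0.5]))
        assert np.allclose(s_hat.ravel(), S[:, 2])

    def test_matches_weighted_sum_loop(self, rng):
        C, S = rng.normal(size=(2, 3)), rng.normal(size=(2, 4))
        a_s, a_c = _softmax(rng.normal(size=4)), _softmax(rng.normal(size=3))
        s_hat, c_hat, _ = attend_and_fuse(C, S, a_s, a_c)
        assert np.allclose(s_hat.ravel(), sum(a_s[j] * S[:, j] for j in range(4)), atol=1e-6)
        assert np.allclose(c_hat.ravel(), sum(a_c[i] * C[:, i] for i in range(3)), atol=1e-6)

    def test_convex_hull_property(self, rng):
        C, S = rng.normal(size=(4, 5)), rng.normal(size=(4, 6))
        a_s, a_c = _softmax(rng.normal(size=6)), _softmax(rng.normal(size=5))
        s_hat, c_hat, _ = attend_and_fuse(C, S, a_s, a_c)
        assert np.all(s_hat.ravel() >= S.min(axis=1) - 1e-12)
        assert np.all(s_hat.ravel() <= S.max(axis=1) + 1e-12)
        assert np.all(c_hat.ravel() >= C.min(axis=1) - 1e-12)
        assert np.all(c_hat.ravel() <= C.max(axis=1) + 1e-12)


class TestOracleEquivalence:
    def test_many_random_tiny_instances(self):
        rng = np.random.default_rng(99)
        core_rng = np.random.default_rng(7)
        for _ in range(100):
            d, k, N, T = rng.integers(1, 6, size=4)
            C, S, W_l, W_s, W_c, w_hs, w_hc = _random_instance(rng, d, k, N, T)
            F = compute_affinity(C, S, W_l)
            H_s, H_c, a_s, a_c = compute_attention_distributions(
                C, S, F, W_s, W_c, w_hs, w_hc)
            s_hat, c_hat, p = attend_and_fuse(C, S, a_s, a_c)
            o = coattention_oracle(C, S, W_l, W_s, W_c, w_hs, w_hc)
            for got, want in zip((F, H_s, H_c, a_s.ravel(), a_c.ravel(),
                                  s_hat.ravel(), c_hat.ravel()), o):
                assert np.allclose(got, want, atol=1e-6)


class TestFullModel:
    def test_head_contracts(self, tiny_bundle, small_samples):
        s = small_samples[0]
        clf = CoAttentionModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=1),
                               task="classification", seed=1).eval()
        out = clf(s.token_ids, s.pad_mask, s.image)
        assert out.shape == (1, 2)
        reg = CoAttentionModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=1),
                               task="regression", seed=1).eval()
        out = reg(s.token_ids, s.pad_mask, s.image)
        assert out.shape == (1, 1) and out.data[0, 0] >= 0.0

    def test_eval_mode_determinism(self, small_samples):
        s = small_samples[0]
        m = CoAttentionModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=2),
                             task="classification", seed=2).eval()
        a = m(s.token_ids, s.pad_mask, s.image).data
        b = m(s.token_ids, s.pad_mask, s.image).data
        assert np.array_equal(a, b)

    def test_forward_equals_manual_composition(self, small_samples):
        s = small_samples[0]
        bundle = dm.build_tiny_encoders(d=16, N=64, T=5, seed=3)
        m = CoAttentionModel(bundle, task="classification", k=4, seed=3).eval()
        out = m(s.token_ids, s.pad_mask, s.image).data
        # manual composition through the functional ops + head
        C = bundle.text_encoder(s.token_ids, s.pad_mask).data.T
        S = bundle.image_encoder(s.image).data.T
        F = compute_affinity(C, S, m.core.W_l.data)
        _, _, a_s, a_c = compute_attention_distributions(
            C, S, F, m.core.W_s.data, m.core.W_c.data,
            m.core.w_hs.data, m.core.w_hc.data)
        _, _, p = attend_and_fuse(C, S, a_s, a_c)
        h = np.maximum(p @ m.fc.weight.data + m.fc.bias.data, 0.0)
        manual = h @ m.out.weight.data + m.out.bias.data
        assert np.allclose(out, manual, atol=1e-5)

    def test_gradient_reaches_every_core_parameter(self, small_samples):
        import demfusion.nn as nn
        s = small_samples[0]
        m = CoAttentionModel(dm.build_tiny_encoders(d=8, N=64, T=5, seed=4),
                             task="classification", k=3, seed=4)
        before = {n: p.data.copy() for n, p in m.core.named_parameters()}
        loss = nn.cross_entropy(m(s.token_ids, s.pad_mask, s.image), [1])
        opt = nn.Adam(m.parameters(), lr=1e-2)
        opt.zero_grad()
        loss.backward()
        opt.step()
        for n, p in m.core.named_parameters():
            assert not np.array_equal(p.data, before[n]), f"dead parameter {n}"
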
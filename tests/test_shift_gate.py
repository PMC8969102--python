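"""Multimodal shifting gate: gates, shift vector, alpha scaling, full model."""

import numpy as np
import pytest

import demfusion as dm
from demfusion._tensor import Tensor
from demfusion.shift_gate import (EPSILON, MultimodalShiftModel, ShiftGate,
                                  ShiftGateConfigError, compute_gates,
                                  compute_shift_vector, scale_and_shift)


class TestGates:
    def test_zero_weights_give_half(self):
        g = compute_gates(np.ones(3), np.ones(2), np.zeros((4, 5)), np.zeros(4))
        assert np.allclose(g, 0.5)

    def test_large_bias_saturates(self):
        g = compute_gates(np.ones(2), np.ones(2), np.zeros((3, 4)), np.full(3, 20.0))
        assert np.all(g > 0.999999)

    def test_matches_loop_oracle(self, rng):
        h, e = rng.normal(size=3), rng.normal(size=3)
        W, b = rng.normal(size=(3, 6)), rng.normal(size=3)
        g = compute_gates(h, e, W, b)
        v = np.concatenate([h, e])
        for i in range(3):
            z = sum(W[i, j] * v[j] for j in range(6)) + b[i]
            assert abs(g[i] - 1.0 / (1.0 + np.exp(-z))) < 1e-6

    def test_entries_strictly_in_unit_interval(self, rng):
        g = compute_gates(rng.normal(size=4), rng.normal(size=4),
                          rng.normal(size=(4, 8)), rng.normal(size=4))
        assert np.all((g > 0) & (g < 1))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_gates(np.ones(3), np.ones(3), np.zeros((2, 4)), np.zeros(2))


class TestShiftVector:
    def test_zero_projections_and_bias_give_zero_shift(self, rng):
        h_m = compute_shift_vector(rng.normal(size=3), rng.normal(size=4),
                                   rng.random(3), rng.random(3),
                                   np.zeros((3, 3)), np.zeros((3, 4)),
                                   np.zeros(3), variant="both")
        assert np.allclose(h_m, 0.0)

    def test_visual_variant_ignores_acoustic(self, rng):
        h_v, gate_v = rng.normal(size=3), rng.random(3)
        W_v, b_m = rng.normal(size=(3, 3)), rng.normal(size=3)
        a = compute_shift_vector(h_v, rng.normal(size=4), gate_v, None,
                                 W_v, None, b_m, variant="visual")
        b = compute_shift_vector(h_v, rng.normal(size=4) * 100, gate_v, None,
                                 W_v, None, b_m, variant="visual")
        assert np.allclose(a, b)

    def test_matches_loop_oracle(self, rng):
        d = 3
        h_v, h_a = rng.normal(size=d), rng.normal(size=5)
        gv, ga = rng.random(d), rng.random(d)
        W_v, W_a = rng.normal(size=(d, d)), rng.normal(size=(d, 5))
        b_m = rng.normal(size=d)
        h_m = compute_shift_vector(h_v, h_a, gv, ga, W_v, W_a, b_m, "both")
        for i in range(d):
            want = (gv[i] * sum(W_v[i, j] * h_v[j] for j in range(d))
                    + ga[i] * sum(W_a[i, j] * h_a[j] for j in range(5)) + b_m[i])
            assert abs(h_m[i] - want) < 1e-6

    def test_missing_modality_for_variant_raises(self):
        with pytest.raises(ShiftGateConfigError):
            compute_shift_vector(None, None, None, None, None, None,
                                 np.zeros(3), variant="visual")


class TestScaleAndShift:
    def test_direct_arithmetic_example(self):
        # ||e|| = 4, ||h_m|| = 2, beta = 0.25 -> alpha = min(0.5, 1) = 0.5
        e = np.array([4.0, 0.0])
        h_m = np.array([0.0, 2.0])
        alpha, e_m = scale_and_shift(e, h_m, beta=0.25)
        assert abs(alpha - 0.5) < 1e-9
        assert np.allclose(e_m, e + 0.5 * h_m)

    def test_zero_shift_is_identity_with_capped_alpha(self):
        e = np.array([1.0, -2.0, 3.0])
        alpha, e_m = scale_and_shift(e, np.zeros(3), beta=0.01)
        assert alpha == 1.0
        assert np.array_equal(e_m, e)

    def test_huge_beta_activates_cap(self, rng):
        e, h_m = rng.normal(size=4), rng.normal(size=4)
        alpha, e_m = scale_and_shift(e, h_m, beta=1e6)
        assert alpha == 1.0
        assert np.allclose(e_m, e + h_m)

    def test_shift_magnitude_bound(self, rng):
        for _ in range(50):
            e, h_m = rng.normal(size=5), rng.normal(size=5)
            beta = float(rng.uniform(0.001, 2.0))
            alpha, e_m = scale_and_shift(e, h_m, beta)
            shift = np.linalg.norm(e_m - e)
            if alpha < 1.0:  # cap inactive
                assert shift <= beta * np.linalg.norm(e) + 1e-9
            else:            # cap active
                assert shift <= np.linalg.norm(h_m) + 1e-9

    def test_beta_continuity_shift_vanishes_monotonically(self, rng):
        e, h_m = rng.normal(size=6), rng.normal(size=6)
        shifts = []
        for beta in [1.0, 0.1, 0.01, 0.001, 1e-4]:
            _, e_m = scale_and_shift(e, h_m, beta)
            shifts.append(np.linalg.norm(e_m - e))
        assert all(a >= b - 1e-12 for a, b in zip(shifts, shifts[1:]))
        assert shifts[-1] < 1e-3 * shifts[0] + 1e-9


class TestGateModule:
    def test_oracle_equivalence_small_instances(self, rng):
        for _ in range(25):
            d = int(rng.integers(2, 5))
            gate = ShiftGate(d, np.random.default_rng(int(rng.integers(1e6))),
                             variant="both", acoustic_dim=3)
            N = int(rng.integers(1, 4))
            e = rng.normal(size=(N, d))
            h_v = rng.normal(size=(N, d))
            h_a = rng.normal(size=(N, 3))
            alpha, h_m, e_m = gate(Tensor(e), Tensor(h_v), Tensor(h_a))
            W_hv = gate.W_hv.weight.data.T
            W_ha = gate.W_ha.weight.data.T
            for i in range(N):
                gv = compute_gates(h_v[i], e[i], W_hv, gate.W_hv.bias.data)
                ga = compute_gates(h_a[i], e[i], W_ha, gate.W_ha.bias.data)
                hm_i = compute_shift_vector(h_v[i], h_a[i], gv, ga,
                                            gate.W_v.weight.data.T,
                                            gate.W_a.weight.data.T,
                                            gate.b_m.data, "both")
                a_i, em_i = scale_and_shift(e[i], hm_i, gate.beta, gate.epsilon)
                assert np.allclose(h_m.data[i], hm_i, atol=1e-6)
                assert abs(alpha.data[i, 0] - a_i) < 1e-6
                assert np.allclose(e_m.data[i], em_i, atol=1e-6)


class TestFullModel:
    def test_zero_shift_reduction(self, small_samples):
        s = small_samples[0]
        bundle = dm.build_tiny_encoders(d=16, N=64, T=5, seed=5)
        m = MultimodalShiftModel(bundle, task="classification", variant="both",
                                 seed=5).eval()
        # zero out every gate/projection weight and bias
        for comp in (m.gate.W_hv, m.gate.W_ha, m.gate.W_v, m.gate.W_a):
            comp.weight.data[:] = 0.0
            if comp.bias is not None:
                comp.bias.data[:] = 0.0
        m.gate.b_m.data[:] = 0.0
        out = m(s.token_ids, s.pad_mask, s.image, s.acoustic).data
        # manual: feed layer-normalized frozen embeddings straight through
        e = m.frozen_encoder(s.token_ids, s.pad_mask)
        h = m.second_encoder.forward_embeddings(m.ln(e), s.pad_mask)
        z = (h.data[0:1] @ m.fc.weight.data + m.fc.bias.data)
        manual = np.maximum(z, 0) @ m.out.weight.data + m.out.bias.data
        assert np.allclose(out, manual, atol=1e-8)

    def test_tiled_modality_rows_identical(self, small_samples):
        s = small_samples[0]
        bundle = dm.build_tiny_encoders(d=16, N=64, T=5, seed=6)
        m = MultimodalShiftModel(bundle, task="classification", variant="both", seed=6)
        pooled = m.image_encoder(s.image).data[0:1]
        from demfusion.acoustic import tile_rows
        tiled = tile_rows(Tensor(pooled), 64).data
        assert tiled.shape == (64, 16)
        assert np.allclose(tiled, pooled)

    def test_eval_determinism(self, small_samples):
        s = small_samples[0]
        m = MultimodalShiftModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=7),
                                 task="regression", variant="acoustic", seed=7).eval()
        a = m(s.token_ids, s.pad_mask, s.image, s.acoustic).data
        b = m(s.token_ids, s.pad_mask, s.image, s.acoustic).data
        assert np.array_equal(a, b)
        assert a[0, 0] >= 0.0

    def test_variant_requires_modality(self, small_samples):
        s = small_samples[0]
        m = MultimodalShiftModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=8),
                                 task="classification", variant="visual", seed=8).eval()
        with pytest.raises(ShiftGateConfigError):
            m(s.token_ids, s.pad_mask, None, s.acoustic)

    def test_default_betas_per_variant(self):
        for variant, beta in [("acoustic", 0.01), ("visual", 0.001), ("both", 0.01)]:
            g = ShiftGate(4, np.random.default_rng(0), variant=variant)
            assert g.beta == beta

    def test_frozen_trainable_split_after_one_step(self, small_samples):
        import demfusion.nn as nn
        s = small_samples[0]
        m = MultimodalShiftModel(dm.build_tiny_encoders(d=16, N=64, T=5, seed=9),
                                 task="classification", variant="both", seed=9)
        frozen_before = m.frozen_encoder.state_dict()
        second_before = m.second_encoder.state_dict()
        loss = nn.cross_entropy(m(s.token_ids, s.pad_mask, s.image, s.acoustic), [1])
        opt = nn.Adam(m.parameters(), lr=1e-2)
        loss.backward()
        opt.step()
        for k, v in m.frozen_encoder.state_dict().items():
            assert np.array_equal(v, frozen_before[k])  # bit-identical
        assert any(not np.array_equal(v, second_before[k])
                   for k, v in m.second_encoder.state_dict().items())
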
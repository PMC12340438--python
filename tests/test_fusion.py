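"""Key-waveform attention, phase gating, and the classification head."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seiznet import (PhaseNetParams, WaveformKernel, align_to_scale, classify,
                     hybrid_kernel, phase_difference, phase_gate_fuse,
                     waveform_attention, waveform_similarity)
from seiznet.autograd import Tensor
from seiznet.fusion import impulse_kernel


def naive_correlation(x, kernel):
    """Per-position dot-product oracle with replicate padding."""
    p = len(kernel) // 2
    xp = np.concatenate([np.repeat(x[:, :1], p, axis=1), x,
                         np.repeat(x[:, -1:], p, axis=1)], axis=1)
    out = np.zeros_like(x)
    for b in range(x.shape[0]):
        for t in range(x.shape[1]):
            out[b, t] = float(np.dot(xp[b, t:t + len(kernel)], kernel))
    return out


class TestHybridKernel:
    def test_pure_impulse_softmax(self):
        # alpha=0, k=3: K_t = [0,1,0] -> softmax ~ [0.2119, 0.5761, 0.2119]
        out = hybrid_kernel(np.array([5.0, -2.0, 1.0]), impulse_kernel(3), 0.0)
        assert np.allclose(out, [0.2119, 0.5761, 0.2119], atol=1e-4)

    def test_pure_learnable_ignores_impulse(self, rng):
        W_b = rng.normal(size=5)
        a = hybrid_kernel(W_b, impulse_kernel(5), 1.0)
        b = hybrid_kernel(W_b, np.roll(impulse_kernel(5), 1), 1.0)
        assert np.allclose(a, b)
        expected = np.exp(np.tanh(W_b)) / np.exp(np.tanh(W_b)).sum()
        assert np.allclose(a, expected, atol=1e-7)

    @given(seed=st.integers(0, 999), alpha=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_always_normalised_and_positive(self, seed, alpha):
        W_b = np.random.default_rng(seed).normal(size=7)
        out = hybrid_kernel(W_b, impulse_kernel(7), alpha)
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out > 0).all()

    def test_alpha_clamped_outside_unit_interval(self, rng):
        W_b = rng.normal(size=5)
        K0 = impulse_kernel(5)
        assert np.allclose(hybrid_kernel(W_b, K0, 1.0), hybrid_kernel(W_b, K0, 3.7))
        assert np.allclose(hybrid_kernel(W_b, K0, 0.0), hybrid_kernel(W_b, K0, -2.0))


class TestWaveformSimilarity:
    def test_constant_signal_with_unit_mass_kernel(self, rng):
        k = rng.dirichlet(np.ones(15))
        assert len(k) // 2 == 7  # pad p = floor(15/2)
        sim = waveform_similarity(np.full((2, 40), 3.0), k)
        assert np.allclose(sim, 3.0, atol=1e-6)

    def test_centre_impulse_is_identity(self, rng):
        x = rng.normal(size=(3, 20))
        assert np.allclose(waveform_similarity(x, impulse_kernel(5)), x)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(2, 32))
            k = rng.normal(size=5)
            assert np.abs(waveform_similarity(x, k) - naive_correlation(x, k)).max() < 1e-6

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            waveform_similarity(rng.normal(size=(1, 10)), np.ones(4))


class TestWaveformAttention:
    def test_uniform_scores_divide_by_length(self, rng):
        x = rng.normal(size=(2, 10))
        assert np.allclose(waveform_attention(x, np.ones_like(x)), x / 10)

    def test_scale_preserving_flag_keeps_magnitude(self, rng):
        x = rng.normal(size=(2, 10))
        assert np.allclose(waveform_attention(x, np.ones_like(x),
                                              scale_preserving=True), x)

    def test_dominant_spike_concentrates_mass(self):
        S = np.zeros((1, 8))
        S[0, 3] = 50.0
        x = np.ones((1, 8))
        out = waveform_attention(x, S)
        assert out[0, 3] > 0.999
        assert np.abs(np.delete(out, 3)).max() < 1e-6

    def test_attention_rows_sum_to_one(self, rng):
        from seiznet.autograd import softmax
        S = rng.normal(size=(4, 16))
        assert np.allclose(softmax(Tensor(S), axis=-1).data.sum(axis=1), 1.0,
                           atol=1e-6)


class TestAlignToScale:
    def test_identity_alignment_channel(self, rng):
        x = rng.normal(size=(2, 12))
        W = np.zeros((1, 4))
        W[0, 0] = 1.0
        out = align_to_scale(x, 12, (W, np.zeros(4)))
        assert out.shape == (2, 12, 4)
        assert np.allclose(out[..., 0], x)
        assert np.abs(out[..., 1:]).max() == 0.0

    def test_constant_embeds_identically(self, rng):
        out = align_to_scale(np.full((1, 12), 2.0), 4,
                             (rng.normal(size=(1, 3)), rng.normal(size=3)))
        assert np.allclose(out, out[:, :1, :])

    def test_output_shapes_across_scales(self, rng):
        x = rng.normal(size=(3, 24))
        params = (rng.normal(size=(1, 5)), rng.normal(size=5))
        for s in (24, 12, 6):
            assert align_to_scale(x, s, params).shape == (3, s, 5)


class TestPhaseDifference:
    def test_zero_difference_gives_bias(self, rng):
        p = PhaseNetParams.init(embed_dim=6, rng=rng)
        p.b2.data = np.array(1.25)
        A = rng.normal(size=(2, 5, 6))
        out = phase_difference(A, A, p)
        assert np.allclose(out, 1.25, atol=1e-7)

    def test_hand_computed_scalar_case(self):
        # D=2, W1=[1,0]^T, W2=[2]: dP = 2*tanh(0.5) for difference [0.5, 9]
        p = PhaseNetParams(W1=Tensor(np.array([[1.0], [0.0]])),
                           b1=Tensor(np.zeros(1)),
                           W2=Tensor(np.array([[2.0]])), b2=Tensor(0.0))
        A = np.array([[[0.5, 9.0]]])
        out = phase_difference(A, np.zeros_like(A), p)
        assert np.allclose(out, 2 * np.tanh(0.5), atol=1e-7)

    def test_tanh_bounds_offset(self, rng):
        p = PhaseNetParams.init(embed_dim=8, rng=rng)
        A = rng.normal(size=(2, 6, 8)) * 100
        X = rng.normal(size=(2, 6, 8)) * 100
        bound = np.abs(p.W2.data).sum() + 1e-9
        assert (np.abs(phase_difference(A, X, p) - p.b2.data) <= bound).all()


class TestPhaseGateFuse:
    def test_zero_offset_is_midpoint(self, rng):
        A, X = rng.normal(size=(2, 4, 3)), rng.normal(size=(2, 4, 3))
        out = phase_gate_fuse(A, X, np.zeros((2, 4, 1)))
        assert np.allclose(out, (A + X) / 2, atol=1e-7)

    def test_gate_saturation_selects_one_input(self, rng):
        A, X = rng.normal(size=(1, 3, 2)), rng.normal(size=(1, 3, 2))
        assert np.allclose(phase_gate_fuse(A, X, np.full((1, 3, 1), 50.0)), A, atol=1e-6)
        assert np.allclose(phase_gate_fuse(A, X, np.full((1, 3, 1), -50.0)), X, atol=1e-6)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=60, deadline=None)
    def test_output_is_convex_combination(self, seed):
        r = np.random.default_rng(seed)
        A, X = r.normal(size=(2, 5, 4)), r.normal(size=(2, 5, 4))
        dP = r.normal(size=(2, 5, 1)) * 3
        out = phase_gate_fuse(A, X, dP)
        lo, hi = np.minimum(A, X), np.maximum(A, X)
        assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()


class TestClassify:
    def _head(self, in_dim, rng=None, zero=False):
        if zero:
            return (np.zeros((in_dim, 2)), np.zeros(2))
        return (rng.normal(size=(in_dim, 2)), rng.normal(size=2))

    def test_zero_head_gives_uniform_probabilities(self, rng):
        feats = [rng.normal(size=(3, 6, 4)), rng.normal(size=(3, 2, 4))]
        probs = classify(feats, self._head(8, zero=True))
        assert np.allclose(probs, 0.5)

    def test_two_class_softmax_value(self):
        # logits [2, 0] -> probs ~ [0.8808, 0.1192]
        feats = [np.ones((1, 1, 1))]
        probs = classify(feats, (np.array([[2.0, 0.0]]), np.zeros(2)))
        assert np.allclose(probs, [[0.8808, 0.1192]], atol=1e-4)

    def test_rows_sum_to_one(self, rng):
        feats = [rng.normal(size=(5, 4, 3))]
        probs = classify(feats, self._head(3, rng))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_feature_list_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one"):
            classify([], self._head(3, rng))

    def test_flatten_reduction_shape(self, rng):
        feats = [rng.normal(size=(2, 4, 3))]
        probs = classify(feats, self._head(12, rng), head_reduction="flatten")
        assert probs.shape == (2, 2)


def test_mcpa_chain_is_deterministic(rng):
    """Full waveform->phase->fuse->classify path is bitwise reproducible."""
    kernel = WaveformKernel.init(k=7, alpha_init=0.5, rng=rng)
    phase = PhaseNetParams.init(embed_dim=4, rng=rng)
    align = (rng.normal(size=(1, 4)), rng.normal(size=4))
    head = (rng.normal(size=(4, 2)), rng.normal(size=2))
    x = rng.normal(size=(2, 16))
    A_i = rng.normal(size=(2, 8, 4))

    def run():
        K = hybrid_kernel(kernel.base.data, kernel.impulse, float(kernel.alpha.data))
        enhanced = waveform_attention(x, waveform_similarity(x, K))
        X_i = align_to_scale(enhanced, 8, align)
        fused = phase_gate_fuse(A_i, X_i, phase_difference(A_i, X_i, phase))
        return classify([fused], head)

    assert np.array_equal(run(), run())
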
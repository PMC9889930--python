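"""Unit and property tests for the seven per-epoch features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegdr import features as F
from eegdr._errors import DegenerateInputError, ValidationError
from eegdr.io import Epoch
from eegdr.synthetic import gen_colored_noise, gen_white_noise

from oracles import dfa_literal, higuchi_literal


class TestMoments:
    def test_maximum(self):
        assert F.maximum([1, 5, -3]) == 5
        assert F.maximum(np.full(10, 2.5)) == 2.5
        x = gen_white_noise(10_000, 1)
        assert F.maximum(x) == max(float(v) for v in x)  # linear-scan oracle

    def test_variance(self):
        assert F.variance([1, -1]) == pytest.approx(2.0)
        assert F.variance(np.full(10, 3.0)) == 0.0
        x = np.random.default_rng(2).standard_normal(100_000)
        assert F.variance(x) == pytest.approx(1.0, rel=0.05)

    def test_kurtosis_hand_value(self):
        # n=4, mean 0, SD^2 = 4/3: (1/3)*4/(4/3)^2 - 3 = -2.25
        assert F.kurtosis([1, -1, 1, -1]) == pytest.approx(-2.25)

    def test_kurtosis_gaussian_centered_on_zero(self):
        vals = [F.kurtosis(np.random.default_rng(s).standard_normal(10_000))
                for s in range(100)]
        assert abs(np.mean(vals)) < 0.05

    def test_kurtosis_degenerate(self):
        with pytest.raises(DegenerateInputError):
            F.kurtosis(np.full(10, 1.0))

    def test_skewness(self):
        assert F.skewness([-2, -1, 0, 1, 2]) == 0.0
        assert F.skewness([0, 0, 0, 1]) > 0
        # moment oracle for [0,0,0,1]: m2=3/16, m3=3/32 -> m3/m2^1.5
        m2, m3 = 3 / 16, 3 / 32
        assert F.skewness([0, 0, 0, 1]) == pytest.approx(m3 / m2 ** 1.5)
        sym = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert abs(F.skewness(sym)) < 1e-12

    def test_short_input_errors(self):
        with pytest.raises(ValidationError):
            F.variance([1.0])
        with pytest.raises(ValidationError):
            F.maximum([])


class TestDFA:
    def test_white_noise_exponent(self):
        alphas = [F.dfa(gen_white_noise(4096, s)).alpha for s in range(1, 51)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_integrated_white_noise_exponent(self):
        alphas = [F.dfa(np.cumsum(gen_white_noise(2048, s))).alpha
                  for s in range(5)]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    def test_matches_literal_reference(self):
        for s in range(20):
            n = int(np.random.default_rng(100 + s).integers(512, 2049))
            x = gen_colored_noise(n, float(s % 3) / 2, seed=s)
            res = F.dfa(x)
            alpha_ref, F_ref = dfa_literal(x, res.box_sizes)
            assert res.alpha == pytest.approx(alpha_ref, abs=1e-10)
            np.testing.assert_allclose(res.fluctuations, F_ref, atol=1e-10)

    def test_fluctuation_grows_with_box_size(self):
        F_mean = np.mean([F.dfa(gen_white_noise(4096, s)).fluctuations
                          for s in range(10)], axis=0)
        assert np.all(np.diff(F_mean) > 0)

    def test_noise_class_ordering(self):
        means = {}
        for beta in (0.0, 1.0, 2.0):
            means[beta] = np.mean([F.dfa(gen_colored_noise(2048, beta, s)).alpha
                                   for s in range(50)])
        assert means[0.0] < means[1.0] < means[2.0]

    def test_result_invariants(self):
        res = F.dfa(gen_white_noise(1024, 3))
        assert len(res.box_sizes) == len(res.fluctuations) >= 4
        assert np.all(res.fluctuations > 0)
        assert np.all(np.diff(res.box_sizes) > 0) and res.box_sizes[0] >= 4
        assert 0 <= res.r_squared <= 1

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            F.dfa(np.zeros(32))
        with pytest.raises(Exception):
            F.dfa(gen_white_noise(256, 0), box_sizes=[4, 8])  # <4 sizes


class TestHiguchi:
    def test_sinusoid_near_one(self):
        t = np.arange(1000) / 250.0
        res = F.higuchi_fd(np.sin(2 * np.pi * 5 * t))
        assert res.dimension == pytest.approx(1.0, abs=0.1)

    def test_white_noise_near_two(self):
        dims = [F.higuchi_fd(gen_white_noise(4096, s)).dimension for s in range(5)]
        assert np.mean(dims) == pytest.approx(2.0, abs=0.15)

    def test_matches_literal_reference(self):
        for s in range(20):
            n = int(np.random.default_rng(200 + s).integers(300, 2049))
            x = gen_colored_noise(n, 1.0, seed=1000 + s)
            res = F.higuchi_fd(x, k_max=8)
            dim_ref, L_ref = higuchi_literal(x, 8)
            assert res.dimension == pytest.approx(dim_ref, abs=1e-10)
            np.testing.assert_allclose(res.curve_lengths, L_ref, atol=1e-10)

    def test_parameter_errors(self):
        with pytest.raises(Exception):
            F.higuchi_fd(gen_white_noise(64, 0), k_max=10)  # needs 10*k_max


class TestSpectralEntropy:
    def test_white_noise_near_flat(self):
        res = F.spectral_entropy(gen_white_noise(8192, 3), 250.0)
        assert res.entropy > 0.95
        assert res.normalized_power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_peaky(self):
        t = np.arange(8192) / 250.0
        assert F.spectral_entropy(np.sin(2 * np.pi * 10 * t), 250.0).entropy < 0.3

    def test_amplitude_invariance(self):
        x = gen_white_noise(2048, 5)
        a = F.spectral_entropy(x, 250.0).entropy
        b = F.spectral_entropy(10 * x, 250.0).entropy
        assert a == pytest.approx(b, abs=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            F.spectral_entropy(np.ones(1024), 250.0)


class TestInvarianceProperties:
    """Translation/scale behaviour of the full feature set."""

    @given(st.integers(0, 1000), st.floats(-50, 50).filter(lambda c: abs(c) > 1e-6))
    @settings(max_examples=15, deadline=None)
    def test_translation(self, seed, c):
        x = gen_white_noise(1024, seed)
        for fn in (F.variance, F.kurtosis, F.skewness):
            assert fn(x + c) == pytest.approx(fn(x), rel=1e-9, abs=1e-9)
        assert F.dfa(x + c).alpha == pytest.approx(F.dfa(x).alpha, rel=1e-9)
        assert F.higuchi_fd(x + c).dimension == pytest.approx(
            F.higuchi_fd(x).dimension, rel=1e-9)
        assert F.spectral_entropy(x + c, 250.0).entropy == pytest.approx(
            F.spectral_entropy(x, 250.0).entropy, rel=1e-6)
        assert F.maximum(x + c) == pytest.approx(F.maximum(x) + c)

    @given(st.integers(0, 1000), st.floats(0.01, 100))
    @settings(max_examples=15, deadline=None)
    def test_positive_scaling(self, seed, c):
        x = gen_white_noise(1024, seed)
        assert F.variance(c * x) == pytest.approx(c ** 2 * F.variance(x), rel=1e-9)
        assert F.kurtosis(c * x) == pytest.approx(F.kurtosis(x), rel=1e-9, abs=1e-9)
        assert F.skewness(c * x) == pytest.approx(F.skewness(x), rel=1e-9, abs=1e-9)
        assert F.dfa(c * x).alpha == pytest.approx(F.dfa(x).alpha, rel=1e-9)
        assert F.higuchi_fd(c * x).dimension == pytest.approx(
            F.higuchi_fd(x).dimension, rel=1e-9)
        assert F.spectral_entropy(c * x, 250.0).entropy == pytest.approx(
            F.spectral_entropy(x, 250.0).entropy, rel=1e-6)


class TestExtraction:
    def test_extract_white_noise_epoch(self):
        ep = Epoch(samples=gen_white_noise(1000, 1), sampling_rate=250.0,
                   channel="c1", subject_id="s1", index=0)
        fv = F.extract_features(ep)
        assert set(fv.values) == set(F.FEATURE_NAMES)
        assert fv.values["dfa_alpha"] == pytest.approx(0.5, abs=0.15)
        assert fv.subject_id == "s1" and fv.channel == "c1"

    def test_constant_epoch_error_names_epoch(self):
        ep = Epoch(samples=np.ones(1000), sampling_rate=250.0,
                   channel="c3", subject_id="s9", index=2)
        with pytest.raises(DegenerateInputError, match="s9"):
            F.extract_features(ep)

    def test_deterministic(self):
        ep = Epoch(samples=gen_white_noise(1000, 4), sampling_rate=250.0,
                   channel="c1", subject_id="s1", index=0)
        assert F.extract_features(ep).values == F.extract_features(ep).values

    def test_batch_matches_single(self):
        """The vectorised table path reproduces per-epoch extraction."""
        eps = [Epoch(samples=gen_white_noise(1000, s), sampling_rate=250.0,
                     channel="c1", subject_id="s1", index=s) for s in range(4)]
        table = F.feature_table(eps)
        for ep in eps:
            fv = F.extract_features(ep)
            sub = table[(table["epoch"] == ep.index)]
            for name in F.FEATURE_NAMES:
                got = float(sub[sub["feature"] == name]["value"].iloc[0])
                assert got == pytest.approx(fv.values[name], rel=1e-12)
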
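"""Generator contracts: determinism, distributional targets, round-trips."""

import numpy as np
import pytest
from scipy import stats

from eegdr import features as F
from eegdr._errors import ParameterError, ValidationError
from eegdr.rhythm import classify_rhythm, cohort_incidence
from eegdr.synthetic import (BandPowerEffect, CohortSpec, ScaleShiftEffect,
                             default_eeg_spec, gen_colored_noise, gen_eeg_cohort,
                             gen_hormone_cohort, gen_scale_cohort, gen_white_noise)


class TestNoise:
    def test_white_determinism_and_variance(self):
        np.testing.assert_array_equal(gen_white_noise(16, 7), gen_white_noise(16, 7))
        x = gen_white_noise(100_000, 3)
        assert x.var() == pytest.approx(1.0, rel=0.05)
        with pytest.raises(ValidationError):
            gen_white_noise(8, 0)

    def test_white_dfa_exponent(self):
        assert F.dfa(gen_white_noise(4096, 1)).alpha == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("beta,target", [(0.0, 0.5), (1.0, 1.0), (2.0, 1.5)])
    def test_colored_noise_dfa_targets(self, beta, target):
        alphas = [F.dfa(gen_colored_noise(4096, beta, s)).alpha for s in range(10)]
        assert np.mean(alphas) == pytest.approx(target, abs=0.1)

    def test_brownian_matches_cumsum_construction(self):
        """Spectrally shaped beta=2 noise scales like integrated white noise."""
        shaped = np.mean([F.dfa(gen_colored_noise(2048, 2.0, s)).alpha
                          for s in range(10)])
        cumsum = np.mean([F.dfa(np.cumsum(gen_white_noise(2048, s))).alpha
                          for s in range(10)])
        assert shaped == pytest.approx(cumsum, abs=0.15)

    def test_beta_zero_distributionally_white(self):
        a = gen_colored_noise(10_000, 0.0, 1)
        b = gen_white_noise(10_000, 2)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_exponent_range_checked(self):
        with pytest.raises(ParameterError):
            gen_colored_noise(1024, 2.5, 0)


class TestEEGCohort:
    SPEC = CohortSpec(n_per_group=3, n_channels=4, sampling_rate=250.0,
                      duration=8.0, effect=BandPowerEffect(channels=(0, 1)),
                      seed=9)

    def test_shapes_and_labels(self):
        cohort = gen_eeg_cohort(self.SPEC)
        assert len(cohort.recordings) == 6
        assert list(np.bincount(cohort.labels)) == [3, 3]
        assert cohort.recordings[0].data.shape == (4, 2000)

    def test_seed_determinism(self):
        a, b = gen_eeg_cohort(self.SPEC), gen_eeg_cohort(self.SPEC)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.recordings[4].data, b.recordings[4].data)

    def test_effect_raises_band_power(self):
        cohort = gen_eeg_cohort(self.SPEC)
        def band_power(rec, ch):
            f, P = __import__("scipy.signal", fromlist=["welch"]).welch(
                rec.data[ch], fs=250.0, nperseg=512)
            return P[(f >= 8) & (f <= 13)].sum()
        p0 = np.mean([band_power(r, 0) for r, l in
                      zip(cohort.recordings, cohort.labels) if l == 0])
        p1 = np.mean([band_power(r, 0) for r, l in
                      zip(cohort.recordings, cohort.labels) if l == 1])
        assert p1 > 2 * p0

    def test_zero_effect_small_n_warns(self):
        spec = CohortSpec(n_per_group=2, n_channels=2, sampling_rate=250.0,
                          duration=5.0,
                          effect=BandPowerEffect(rel_amplitude=0.0, channels=(0,)),
                          seed=1)
        assert gen_eeg_cohort(spec).meta["warnings"]


class TestScaleCohort:
    def test_group_means_near_targets(self):
        spec = CohortSpec(n_per_group=21, n_channels=1, sampling_rate=1.0,
                          duration=1.0, effect=ScaleShiftEffect("hamd"), seed=2)
        df = gen_scale_cohort(spec)
        for g, mu, sd in [(0, 31.81, 5.39), (1, 25.25, 5.02)]:
            tot = df[df["group"] == g]["total"]
            assert abs(tot.mean() - mu) < 2 * sd / np.sqrt(21)

    def test_totals_in_instrument_range(self):
        spec = CohortSpec(n_per_group=40, n_channels=1, sampling_rate=1.0,
                          duration=1.0,
                          effect=ScaleShiftEffect("tas", 90, 15, 30, 15), seed=3)
        df = gen_scale_cohort(spec)
        assert df["total"].between(20, 100).all()
        items = df[[f"item_{i}" for i in range(1, 21)]]
        assert items.min().min() >= 1 and items.max().max() <= 5

    def test_item_sums_match_total_and_determinism(self):
        spec = CohortSpec(n_per_group=5, n_channels=1, sampling_rate=1.0,
                          duration=1.0, effect=ScaleShiftEffect("hamd"), seed=4)
        df = gen_scale_cohort(spec)
        items = df[[f"item_{i}" for i in range(1, 25)]]
        assert (items.sum(axis=1) == df["total"]).all()
        assert gen_scale_cohort(spec).equals(df)

    def test_unachievable_mean_rejected(self):
        spec = CohortSpec(n_per_group=5, n_channels=1, sampling_rate=1.0,
                          duration=1.0,
                          effect=ScaleShiftEffect("tas", mean_a=150.0), seed=0)
        with pytest.raises(ParameterError):
            gen_scale_cohort(spec)


class TestHormoneCohort:
    @pytest.mark.parametrize("frac", [0.0, 0.51, 0.72, 1.0])
    def test_round_trip_exact(self, frac):
        profiles = gen_hormone_cohort(100, frac, seed=5)
        disturbed = sum(classify_rhythm(p).disturbed for p in profiles)
        assert disturbed == round(100 * frac)

    def test_incidence_summary(self):
        profs = gen_hormone_cohort(100, 0.72, 1) + gen_hormone_cohort(100, 0.51, 2)
        inc = cohort_incidence(profs, ["A"] * 100 + ["NA"] * 100)
        assert inc["incidence"]["COR"] == {"A": 0.72, "NA": 0.51}

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            gen_hormone_cohort(0, 0.5, 0)

    def test_determinism(self):
        a = gen_hormone_cohort(20, 0.4, 6)
        b = gen_hormone_cohort(20, 0.4, 6)
        assert [(p.subject_id, p.c8) for p in a] == [(p.subject_id, p.c8) for p in b]


def test_default_spec_is_study_configuration():
    spec = default_eeg_spec(seed=1)
    assert (spec.sampling_rate, spec.n_channels, spec.duration) == (250.0, 16, 60.0)
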
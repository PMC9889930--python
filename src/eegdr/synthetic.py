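"""Synthetic study data: noise oracles, EEG cohorts, scale responses, hormones.

Every generator is a pure function of its arguments including the seed, so a
cohort can be regenerated bit-for-bit from its metadata.

* :func:`gen_white_noise` / :func:`gen_colored_noise` produce series with
  analytically known DFA exponents (alpha = (beta + 1) / 2 for a 1/f^beta
  spectrum: 0.5 white, ~1.0 pink, ~1.5 Brownian-like) — oracle inputs for
  the feature estimators.
* :func:`gen_eeg_cohort` builds a two-group resting-EEG cohort on a common
  pink-noise background, injecting an additive narrow-band (default
  8–13 Hz alpha) sinusoidal component on designated channels of one group.
* :func:`gen_scale_cohort` produces item-level HAMD-24 / TAS-20 response
  tables whose totals follow configured group means and SDs.
* :func:`gen_hormone_cohort` builds three-timepoint hormone profiles with an
  exact, constructed fraction of circadian-rhythm-disordered subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import ParameterError, ValidationError
from .io import Recording
from .rhythm import HormoneProfile, classify_rhythm
from .scales import hamd_item_ranges, DEFAULT_HAMD_CONFIG, TAS_N_ITEMS

__all__ = [
    "BandPowerEffect", "ScaleShiftEffect", "CohortSpec", "EEGCohort",
    "gen_white_noise", "gen_colored_noise", "gen_eeg_cohort",
    "gen_scale_cohort", "gen_hormone_cohort", "default_eeg_spec",
]


# ---------------------------------------------------------------------------
# effect descriptors and cohort specification

@dataclass(frozen=True)
class BandPowerEffect:
    """Additive narrow-band power increase on selected channels of group 1.

    ``rel_amplitude`` is the sinusoid amplitude relative to the background
    SD of the channel; 0 means no group difference.
    """
    low_hz: float = 8.0
    high_hz: float = 13.0
    rel_amplitude: float = 1.0
    channels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ScaleShiftEffect:
    """Group mean shift on questionnaire totals."""
    instrument: Literal["hamd", "tas"] = "hamd"
    mean_a: float = 31.81
    sd_a: float = 5.39
    mean_b: float = 25.25
    sd_b: float = 5.02


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description; identical spec (incl. seed) regenerates
    the identical cohort."""
    n_per_group: int
    n_channels: int
    sampling_rate: float
    duration: float
    effect: object
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ParameterError("sampling_rate and duration must be positive")


def default_eeg_spec(seed: int = 0, n_per_group: int = 30,
                     effect: BandPowerEffect | None = None) -> CohortSpec:
    """Study-default EEG cohort: 250 Hz, 16 channels, 60 s per recording."""
    return CohortSpec(n_per_group=n_per_group, n_channels=16,
                      sampling_rate=250.0, duration=60.0,
                      effect=BandPowerEffect() if effect is None else effect,
                      seed=seed)


@dataclass
class EEGCohort:
    recordings: list[Recording]
    labels: np.ndarray          # 1 = affected group, 0 = comparison group
    meta: dict


# ---------------------------------------------------------------------------
# noise oracles

def gen_white_noise(n: int, seed: int) -> np.ndarray:
    """i.i.d. standard Gaussian series of length n (n >= 16)."""
    if n < 16:
        raise ValidationError("white noise length must be >= 16")
    return np.random.default_rng(seed).standard_normal(n)


def gen_colored_noise(n: int, exponent: float, seed: int) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent via FFT shaping.

    exponent in [0, 2]; 0 reduces to white noise, 1 is pink, 2 Brownian-like.
    Output is standardised to zero mean and unit variance.
    """
    if n < 64:
        raise ValidationError("colored noise length must be >= 64")
    if not 0 <= exponent <= 2:
        raise ParameterError("spectral exponent must be in [0, 2]")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    if exponent == 0:
        return w
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return (x - x.mean()) / x.std()


# ---------------------------------------------------------------------------
# EEG cohorts

def _pink_background(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        out[c] = gen_colored_noise(n, 1.0, int(rng.integers(0, 2 ** 31)))
    return out


def gen_eeg_cohort(spec: CohortSpec) -> EEGCohort:
    """Two groups of multichannel recordings on a pink-noise background.

    Group 1 receives the additive band-limited sinusoidal component described
    by the spec's :class:`BandPowerEffect`; group 0 is background only.
    Background SD ~10 uV with per-subject lognormal jitter; the effect
    amplitude carries mild per-subject jitter so subjects are not clones.
    """
    eff = spec.effect
    if not isinstance(eff, BandPowerEffect):
        raise ParameterError("gen_eeg_cohort requires a BandPowerEffect")
    if any(c < 0 or c >= spec.n_channels for c in eff.channels):
        raise ParameterError("effect channel index out of range")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    recordings: list[Recording] = []
    labels = []
    meta: dict = {"seed": spec.seed, "spec": spec, "warnings": []}
    if eff.rel_amplitude == 0 and spec.n_per_group < 4:
        meta["warnings"].append("zero effect with n_per_group < 4: groups are exchangeable noise")
    for group in (0, 1):
        for s in range(spec.n_per_group):
            sigma = 10.0 * np.exp(rng.normal(0.0, 0.15))
            data = sigma * _pink_background(rng, spec.n_channels, n)
            if group == 1 and eff.rel_amplitude > 0:
                amp = eff.rel_amplitude * sigma * max(0.3, rng.normal(1.0, 0.25))
                freq = rng.uniform(eff.low_hz, eff.high_hz)
                for c in eff.channels:
                    phase = rng.uniform(0, 2 * np.pi)
                    data[c] += amp * np.sin(2 * np.pi * freq * t + phase)
            sid = f"g{group}_s{s:03d}"
            recordings.append(Recording(
                channels=[f"ch{c:02d}" for c in range(spec.n_channels)],
                data=data, sampling_rate=spec.sampling_rate, subject_id=sid))
            labels.append(group)
    return EEGCohort(recordings=recordings, labels=np.array(labels), meta=meta)


# ---------------------------------------------------------------------------
# questionnaire cohorts

def _items_for_total(rng: np.random.Generator, target: int,
                     lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Random item vector within [lo, hi] per item summing exactly to target."""
    items = lo.copy()
    budget = target - int(lo.sum())
    headroom = hi - items
    while budget > 0:
        open_idx = np.flatnonzero(headroom > 0)
        i = rng.choice(open_idx)
        items[i] += 1
        headroom[i] -= 1
        budget -= 1
    return items


def gen_scale_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Item-level questionnaire responses with configured group total means/SDs.

    Per subject a target total is drawn from N(mean_g, sd_g), rounded and
    clipped to the instrument's admissible total range, then distributed over
    items by random unit increments within per-item ranges (so the total is
    exact by construction).  Returns a frame with item_1..item_K, total,
    group and subject_id columns.
    """
    eff = spec.effect
    if not isinstance(eff, ScaleShiftEffect):
        raise ParameterError("gen_scale_cohort requires a ScaleShiftEffect")
    if eff.instrument == "hamd":
        ranges = hamd_item_ranges(DEFAULT_HAMD_CONFIG)
        lo = np.array([r[0] for r in ranges])
        hi = np.array([r[1] for r in ranges])
    elif eff.instrument == "tas":
        # raw (pre-reverse) responses are 1..5 for all 20 items
        lo = np.full(TAS_N_ITEMS, 1)
        hi = np.full(TAS_N_ITEMS, 5)
    else:
        raise ParameterError(f"unknown instrument {eff.instrument!r}")
    tmin, tmax = int(lo.sum()), int(hi.sum())
    for mean in (eff.mean_a, eff.mean_b):
        if not tmin <= mean <= tmax:
            raise ParameterError(
                f"requested mean {mean} outside achievable total range [{tmin}, {tmax}]")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, (mu, sd) in enumerate([(eff.mean_a, eff.sd_a), (eff.mean_b, eff.sd_b)]):
        for s in range(spec.n_per_group):
            target = int(np.clip(round(rng.normal(mu, sd)), tmin, tmax))
            items = _items_for_total(rng, target, lo, hi)
            rows.append({"subject_id": f"g{group}_s{s:03d}", "group": group,
                         **{f"item_{i + 1}": int(v) for i, v in enumerate(items)},
                         "total": int(items.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hormone cohorts

def gen_hormone_cohort(n: int, crd_fraction: float, seed: int,
                       analyte: str = "COR") -> list[HormoneProfile]:
    """Three-timepoint hormone profiles with an exact disordered fraction.

    Exactly ``round(n * crd_fraction)`` profiles violate the 50%-decline
    rhythm rule and the rest satisfy it; status is exact by construction
    (decline ratios are drawn strictly inside/outside the threshold) and
    re-verified against the classifier.  Healthy morning cortisol is drawn
    around 400 nmol/L (ACTH around 40 pg/mL), lognormal between subjects.
    """
    if n <= 0:
        raise ParameterError("hormone cohort needs n >= 1")
    if not 0 <= crd_fraction <= 1:
        raise ParameterError("crd_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_disordered = int(round(n * crd_fraction))
    base = 400.0 if analyte.upper() == "COR" else 40.0
    profiles: list[HormoneProfile] = []
    for i in range(n):
        c8 = base * np.exp(rng.normal(0.0, 0.25))
        if i < n_disordered:
            # violate the 16:00-vs-08:00 decline: ratio drawn above threshold
            r16 = rng.uniform(0.55, 1.10)
            r24 = rng.uniform(0.15, 0.45)
        else:
            # clean decline: each later ratio strictly below threshold; the
            # 24v8 ratio is then <= 0.45^2 and cannot trip the pooled rule
            r16 = rng.uniform(0.15, 0.45)
            r24 = rng.uniform(0.15, 0.45)
        p = HormoneProfile(subject_id=f"s{i:03d}", analyte=analyte.upper(),
                           c8=c8, c16=r16 * c8, c24=r24 * r16 * c8)
        assert classify_rhythm(p).disturbed == (i < n_disordered)
        profiles.append(p)
    order = rng.permutation(n)
    return [profiles[j] for j in order]
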
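"""Per-epoch EEG features.

Seven features are computed for every analysis epoch:

========================  =====================================================
``max``                   maximum sample value
``variance``              sample variance, 1/(n-1) denominator
``kurtosis``              excess kurtosis, hybrid estimator
                          ``(1/(n-1)) * sum((x - mean)^4) / SD^4 - 3`` with
                          SD^2 the 1/(n-1) variance (0 for a Gaussian series)
``skewness``              moment estimator ``m3 / m2^(3/2)`` (population
                          denominators; standard sign convention)
``dfa_alpha``             detrended fluctuation analysis scaling exponent
``hfd``                   Higuchi fractal dimension
``spectral_entropy``      normalised Shannon entropy of the Welch power
                          spectrum, in [0, 1]
========================  =====================================================

DFA
---
The series is mean-centred and integrated, ``Y(k) = sum_{i<=k}(x_i - mean)``.
For each box size *n* the integrated profile is split into ``floor(N/n)``
non-overlapping boxes, a linear least-squares trend is removed per box, and

    F(n) = sqrt( mean of squared residuals over all covered points ).

``alpha`` is the slope of the least-squares line of ``log F(n)`` on
``log n`` (natural logs).  White noise gives alpha = 0.5, 1/f noise about
1.0, integrated white noise (Brownian profile) about 1.5.  Box sizes default
to ~12 log-spaced integers from 4 to N/4.

Higuchi fractal dimension
-------------------------
For interval k and offset m (1-based), the curve length is

    L_m(k) = [ sum_{i=1..M} |x(m+ik) - x(m+(i-1)k)| ] * (N-1) / (M*k) / k,
    M = floor((N-m)/k),

L(k) is the mean of L_m(k) over m = 1..k, and the dimension is the negative
slope of ``ln L(k)`` vs ``ln k`` for k = 1..k_max.  Smooth curves approach
1, white noise approaches 2.

Spectral entropy
----------------
Welch PSD (Hann taper, segments of min(N, 256) samples, 50% overlap), DC bin
dropped, normalised to a probability vector p; entropy is
``-sum(p ln p) / ln(n_bins)`` so a flat (white) spectrum scores near 1 and a
line spectrum near 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._errors import DegenerateInputError, EstimationError, ParameterError, ValidationError
from .io import Epoch, Recording, epoch_signal

__all__ = [
    "FEATURE_NAMES", "DFAResult", "HFDResult", "SpectralEntropyResult",
    "FeatureVector", "maximum", "variance", "kurtosis", "skewness",
    "dfa", "default_box_sizes", "higuchi_fd", "spectral_entropy",
    "extract_features", "feature_table", "extract_cohort_features",
]

FEATURE_NAMES = ("max", "variance", "kurtosis", "skewness",
                 "dfa_alpha", "hfd", "spectral_entropy")


# ---------------------------------------------------------------------------
# result containers

@dataclass
class DFAResult:
    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_intercept: float
    r_squared: float


@dataclass
class HFDResult:
    dimension: float
    k_values: np.ndarray
    curve_lengths: np.ndarray
    clipped: bool = False


@dataclass
class SpectralEntropyResult:
    entropy: float
    frequencies: np.ndarray
    normalized_power: np.ndarray


@dataclass
class FeatureVector:
    """The seven named features of one epoch, with provenance."""
    values: dict[str, float]
    subject_id: str = ""
    channel: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        missing = [k for k in FEATURE_NAMES if k not in self.values]
        if missing:
            raise ValidationError(f"feature vector missing {missing}")
        bad = [k for k in FEATURE_NAMES if not np.isfinite(self.values[k])]
        if bad:
            raise ValidationError(f"non-finite feature value(s): {bad}")


# ---------------------------------------------------------------------------
# linear features

def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValidationError("input must be a non-empty 1-D sequence")
    if not np.isfinite(a).all():
        raise ValidationError("input contains non-finite values")
    return a


def maximum(x) -> float:
    """Largest sample value."""
    return float(_as1d(x).max())


def variance(x) -> float:
    """Sample variance with 1/(n-1) denominator."""
    a = _as1d(x)
    if a.size < 2:
        raise ValidationError("variance needs at least 2 samples")
    return float(a.var(ddof=1))


def kurtosis(x) -> float:
    """Excess kurtosis with the hybrid 1/(n-1) estimator.

    ``(1/(n-1)) * sum((x_i - mean)^4) / SD^4 - 3`` where SD^2 is the
    1/(n-1) sample variance; zero for a normally distributed series.
    """
    a = _as1d(x)
    if a.size < 4:
        raise ValidationError("kurtosis needs at least 4 samples")
    sd2 = a.var(ddof=1)
    if sd2 == 0:
        raise DegenerateInputError("kurtosis undefined for zero-variance input")
    n = a.size
    m = a.mean()
    return float(np.sum((a - m) ** 4) / (n - 1) / sd2 ** 2 - 3.0)


def skewness(x) -> float:
    """Moment-estimator skewness ``m3 / m2^(3/2)`` (population denominators).

    Positive when the right tail is heavier; 0 for a symmetric sample.
    """
    a = _as1d(x)
    if a.size < 3:
        raise ValidationError("skewness needs at least 3 samples")
    m = a.mean()
    m2 = np.mean((a - m) ** 2)
    if m2 == 0:
        raise DegenerateInputError("skewness undefined for zero-variance input")
    m3 = np.mean((a - m) ** 3)
    return float(m3 / m2 ** 1.5)


# ---------------------------------------------------------------------------
# DFA

def default_box_sizes(n: int, n_sizes: int = 12) -> np.ndarray:
    """~12 log-spaced integer box sizes from 4 to n/4 (unique, increasing)."""
    if n < 64:
        raise ParameterError("need at least 64 samples for DFA box sizes")
    sizes = np.unique(np.round(np.geomspace(4, n // 4, n_sizes)).astype(int))
    return sizes[sizes >= 4]


def _dfa_batch(X: np.ndarray, box_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DFA fluctuation functions for a batch of series.

    X has shape (E, N).  Returns (F, alpha) with F of shape (E, n_sizes).
    """
    E, N = X.shape
    Y = np.cumsum(X - X.mean(axis=1, keepdims=True), axis=1)
    F = np.empty((E, len(box_sizes)))
    for j, n in enumerate(box_sizes):
        nb = N // n
        seg = Y[:, :nb * n].reshape(E, nb, n)
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        denom = np.sum(tc ** 2)
        slope = seg @ tc / denom                       # (E, nb)
        inter = seg.mean(axis=2)
        resid = seg - inter[:, :, None] - slope[:, :, None] * tc
        F[:, j] = np.sqrt(np.mean(resid ** 2, axis=(1, 2)))
    logn = np.log(box_sizes.astype(float))
    logF = np.log(F)
    lc = logn - logn.mean()
    alpha = logF @ lc / np.sum(lc ** 2)
    return F, alpha


def dfa(x, box_sizes=None) -> DFAResult:
    """Detrended fluctuation analysis scaling exponent (linear detrending).

    Box sizes with fewer than two boxes are dropped with a warning; fewer
    than four usable sizes raises :class:`EstimationError`.
    """
    a = _as1d(x)
    N = a.size
    if N < 64:
        raise ValidationError("DFA needs at least 64 samples")
    if box_sizes is None:
        sizes = default_box_sizes(N)
    else:
        sizes = np.asarray(box_sizes, dtype=int)
        if len(sizes) < 4:
            raise ParameterError("need at least 4 box sizes")
        if np.any(np.diff(sizes) <= 0) or sizes[0] < 4 or sizes[-1] > N // 2:
            raise ParameterError("box sizes must be strictly increasing, in [4, N/2]")
    usable = sizes[N // sizes >= 2]
    if len(usable) < len(sizes):
        warnings.warn(f"dropped {len(sizes) - len(usable)} box size(s) with <2 boxes")
    if len(usable) < 4:
        raise EstimationError("fewer than 4 usable box sizes")
    F, alpha = _dfa_batch(a[None, :], usable)
    F = F[0]
    logn, logF = np.log(usable.astype(float)), np.log(F)
    slope, intercept = np.polyfit(logn, logF, 1)
    pred = slope * logn + intercept
    ss_res = np.sum((logF - pred) ** 2)
    ss_tot = np.sum((logF - logF.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(alpha=float(slope), box_sizes=usable, fluctuations=F,
                     fit_intercept=float(intercept), r_squared=float(r2))


# ---------------------------------------------------------------------------
# Higuchi fractal dimension

def _hfd_batch(X: np.ndarray, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Curve lengths L(k) and dimensions for a batch of series (E, N)."""
    E, N = X.shape
    L = np.empty((E, k_max))
    for k in range(1, k_max + 1):
        Lm = np.zeros(E)
        for m in range(1, k + 1):
            M = (N - m) // k
            idx = m - 1 + np.arange(M + 1) * k
            sub = X[:, idx]
            dist = np.sum(np.abs(np.diff(sub, axis=1)), axis=1)
            Lm += dist * (N - 1) / (M * k) / k
        L[:, k - 1] = Lm / k
    lk = np.log(np.arange(1, k_max + 1, dtype=float))
    lL = np.log(L)
    lc = lk - lk.mean()
    dim = -(lL @ lc) / np.sum(lc ** 2)
    return L, dim


def higuchi_fd(x, k_max: int = 10) -> HFDResult:
    """Higuchi fractal dimension, clipped (and flagged) to [1, 2]."""
    a = _as1d(x)
    if k_max < 2:
        raise ParameterError("k_max must be >= 2")
    if a.size < 10 * k_max:
        raise ParameterError(f"need at least 10*k_max = {10 * k_max} samples")
    L, dim = _hfd_batch(a[None, :], k_max)
    L, dim = L[0], float(dim[0])
    if not np.all(L > 0):
        raise DegenerateInputError("zero curve length (constant signal?)")
    clipped = not (1.0 <= dim <= 2.0)
    return HFDResult(dimension=float(np.clip(dim, 1.0, 2.0)),
                     k_values=np.arange(1, k_max + 1),
                     curve_lengths=L, clipped=clipped)


# ---------------------------------------------------------------------------
# spectral entropy

def _welch_psd(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(X.shape[-1], 256)
    return sps.welch(X, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def spectral_entropy(x, sampling_rate: float) -> SpectralEntropyResult:
    """Normalised Shannon entropy of the Welch power spectrum (DC dropped)."""
    a = _as1d(x)
    if a.size < 128:
        raise ValidationError("spectral entropy needs at least 128 samples")
    if np.all(a == a[0]):
        raise DegenerateInputError("spectral entropy undefined for a constant signal")
    f, P = _welch_psd(a[None, :], sampling_rate)
    f, P = f[1:], P[0, 1:]
    p = P / P.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log(p), 0.0)) / np.log(len(p))
    return SpectralEntropyResult(entropy=float(h), frequencies=f, normalized_power=p)


# ---------------------------------------------------------------------------
# extraction

def _batch_feature_frame(X: np.ndarray, fs: float, k_max: int = 10) -> pd.DataFrame:
    """All seven features for a stack of equal-length epochs (E, N)."""
    E, N = X.shape
    mx = X.max(axis=1)
    var = X.var(axis=1, ddof=1)
    if np.any(var == 0):
        raise DegenerateInputError("kurtosis/skewness undefined: zero-variance epoch present")
    mean = X.mean(axis=1, keepdims=True)
    d = X - mean
    kurt = np.sum(d ** 4, axis=1) / (N - 1) / var ** 2 - 3.0
    m2 = np.mean(d ** 2, axis=1)
    m3 = np.mean(d ** 3, axis=1)
    skew = m3 / m2 ** 1.5
    _, alpha = _dfa_batch(X, default_box_sizes(N))
    _, hdim = _hfd_batch(X, k_max)
    hdim = np.clip(hdim, 1.0, 2.0)
    f, P = _welch_psd(X, fs)
    P = P[:, 1:]
    p = P / P.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1) / np.log(p.shape[1])
    return pd.DataFrame({"max": mx, "variance": var, "kurtosis": kurt,
                         "skewness": skew, "dfa_alpha": alpha, "hfd": hdim,
                         "spectral_entropy": ent})


def extract_features(epoch: Epoch, k_max: int = 10) -> FeatureVector:
    """Compute the seven features of one epoch with module defaults."""
    try:
        row = _batch_feature_frame(epoch.samples[None, :], epoch.sampling_rate,
                                   k_max=k_max).iloc[0]
    except (DegenerateInputError, ValidationError, EstimationError) as exc:
        raise type(exc)(
            f"{exc} (subject={epoch.subject_id!r}, channel={epoch.channel!r}, "
            f"epoch={epoch.index})"
        ) from exc
    return FeatureVector(values={k: float(row[k]) for k in FEATURE_NAMES},
                         subject_id=epoch.subject_id, channel=epoch.channel,
                         epoch_index=epoch.index)


def feature_table(epochs: list[Epoch], k_max: int = 10) -> pd.DataFrame:
    """Tidy table (subject_id, channel, epoch, feature, value) for many epochs.

    Epochs of equal length are processed as vectorised batches.
    """
    rows = []
    by_len: dict[tuple[int, float], list[Epoch]] = {}
    for e in epochs:
        by_len.setdefault((len(e.samples), e.sampling_rate), []).append(e)
    for (_, fs), group in by_len.items():
        X = np.stack([e.samples for e in group])
        frame = _batch_feature_frame(X, fs, k_max=k_max)
        for e, (_, feat) in zip(group, frame.iterrows()):
            for name in FEATURE_NAMES:
                rows.append((e.subject_id, e.channel, e.index, name, feat[name]))
    return pd.DataFrame(rows, columns=["subject_id", "channel", "epoch", "feature", "value"])


def extract_cohort_features(recordings: list[Recording], window_seconds: float = 4.0,
                            overlap_fraction: float = 0.0, k_max: int = 10) -> pd.DataFrame:
    """Epoch every recording and return the tidy per-epoch feature table."""
    epochs: list[Epoch] = []
    for rec in recordings:
        epochs.extend(epoch_signal(rec, window_seconds, overlap_fraction))
    return feature_table(epochs, k_max=k_max)
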
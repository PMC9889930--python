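"""Multichannel recording I/O and epoching.

A :class:`Recording` holds a resting-state multichannel signal (one row per
channel) together with its sampling rate.  Recordings are read and written in
two formats:

* wide CSV — first column ``time`` in seconds, one column per channel,
  header row carries the channel labels;
* EDF (European Data Format) — read through :mod:`mne`; written by a small
  16-bit EDF writer built into this module.  Sample values are interpreted
  as microvolts in both directions.

:func:`epoch_signal` cuts each channel into fixed-length analysis windows
(half-open ``[start, start + L)``, 0-based sample indices); trailing partial
windows are discarded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParameterError, ValidationError

__all__ = ["Recording", "Epoch", "read_recording", "write_recording", "epoch_signal"]

_MIN_EPOCH_SAMPLES = 64


@dataclass
class Recording:
    """A multichannel sampled signal.

    Parameters
    ----------
    channels
        Ordered channel labels.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling frequency in Hz.
    subject_id
        Identifier carried through feature provenance.
    """

    channels: list[str]
    data: np.ndarray
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} labels for {self.data.shape[0]} data rows"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        bad = [c for i, c in enumerate(self.channels) if not np.isfinite(self.data[i]).all()]
        if bad:
            raise ValidationError(f"non-finite samples in channel(s): {', '.join(bad)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Epoch:
    """A fixed-length single-channel analysis window."""

    samples: np.ndarray
    sampling_rate: float
    channel: str
    subject_id: str
    index: int
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("epoch samples must be 1-D")
        if len(self.samples) < _MIN_EPOCH_SAMPLES:
            raise ValidationError(
                f"epoch has {len(self.samples)} samples; minimum is {_MIN_EPOCH_SAMPLES}"
            )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("edf", "csv"):
        return suffix
    raise ParameterError(f"cannot infer format from suffix {path.suffix!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None,
                   subject_id: str | None = None) -> Recording:
    """Read a recording from wide CSV or EDF.

    Channel order is preserved from the file.  Non-finite samples raise a
    :class:`ValidationError` naming the offending channels.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValidationError("wide CSV needs a time column plus >=1 channel column")
        time = df.iloc[:, 0].to_numpy(float)
        if len(time) < 2:
            raise ValidationError("recording too short to infer sampling rate")
        sr = 1.0 / float(np.median(np.diff(time)))
        channels = list(df.columns[1:])
        data = df.iloc[:, 1:].to_numpy(float).T
    elif fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = list(raw.ch_names)
        sr = float(raw.info["sfreq"])
        # mne scales EEG channels to volts internally; recover microvolts.
        data = raw.get_data(units="uV")
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    return Recording(channels=channels, data=data, sampling_rate=sr,
                     subject_id=subject_id if subject_id is not None else path.stem)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as wide CSV or 16-bit EDF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        t = np.arange(rec.n_samples) / rec.sampling_rate
        df = pd.DataFrame({"time": t})
        for i, ch in enumerate(rec.channels):
            df[ch] = rec.data[i]
        df.to_csv(path, index=False)
    elif fmt == "edf":
        _edf_write(rec, path)
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    return path


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_write(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record spanning the whole signal,
    16-bit samples, symmetric physical range per channel set from the
    channel's max absolute value (maximises quantisation resolution)."""
    n_sig = len(rec.channels)
    n_samp = rec.n_samples
    duration = n_samp / rec.sampling_rate
    header_bytes = 256 + 256 * n_sig

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768

    with open(path, "wb") as fh:
        fh.write(_edf_ascii("0", 8))
        fh.write(_edf_ascii(rec.subject_id or "X", 80))
        fh.write(_edf_ascii("Startdate 01-JAN-2000", 80))
        fh.write(_edf_ascii("01.01.00", 8))
        fh.write(_edf_ascii("00.00.00", 8))
        fh.write(_edf_ascii(header_bytes, 8))
        fh.write(_edf_ascii("", 44))
        fh.write(_edf_ascii(1, 8))                       # number of data records
        fh.write(_edf_ascii(f"{duration:.6g}", 8))       # record duration, seconds
        fh.write(_edf_ascii(n_sig, 4))
        for ch in rec.channels:
            fh.write(_edf_ascii(ch, 16))
        for _ in rec.channels:
            fh.write(_edf_ascii("", 80))                 # transducer
        for _ in rec.channels:
            fh.write(_edf_ascii("uV", 8))
        for pm in phys_max:
            fh.write(_edf_ascii(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            fh.write(_edf_ascii(f"{pm:.6g}"[:8], 8))
        for _ in rec.channels:
            fh.write(_edf_ascii(dig_min, 8))
        for _ in rec.channels:
            fh.write(_edf_ascii(dig_max, 8))
        for _ in rec.channels:
            fh.write(_edf_ascii("", 80))                 # prefiltering
        for _ in rec.channels:
            fh.write(_edf_ascii(n_samp, 8))              # samples per record
        for _ in rec.channels:
            fh.write(_edf_ascii("", 32))
        for i in range(n_sig):
            # EDF digital-to-physical map: p = pmin + (d - dmin) * (pmax-pmin)/(dmax-dmin)
            pmin, pmax = -phys_max[i], phys_max[i]
            scale = (dig_max - dig_min) / (pmax - pmin)
            dig = np.round((rec.data[i] - pmin) * scale + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def epoch_signal(rec: Recording, window_seconds: float,
                 overlap_fraction: float = 0.0,
                 channels: list[str] | None = None) -> list[Epoch]:
    """Cut every channel into fixed windows with optional fractional overlap.

    Windows tile each channel with stride ``L * (1 - overlap)``; the trailing
    partial window is discarded, so each channel yields
    ``floor((N - L) / stride) + 1`` epochs.
    """
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must be in [0, 1)")
    L = int(round(window_seconds * rec.sampling_rate))
    if L < _MIN_EPOCH_SAMPLES:
        raise ParameterError(f"window of {L} samples is below the minimum {_MIN_EPOCH_SAMPLES}")
    if L > rec.n_samples:
        raise ParameterError(
            f"window ({L} samples) longer than recording ({rec.n_samples} samples)")
    stride = int(round(L * (1 - overlap_fraction)))
    stride = max(stride, 1)
    wanted = set(channels) if channels is not None else None
    epochs: list[Epoch] = []
    for ci, ch in enumerate(rec.channels):
        if wanted is not None and ch not in wanted:
            continue
        n_ep = (rec.n_samples - L) // stride + 1
        for k in range(n_ep):
            start = k * stride
            epochs.append(Epoch(samples=rec.data[ci, start:start + L],
                                sampling_rate=rec.sampling_rate,
                                channel=ch, subject_id=rec.subject_id,
                                index=k, start_sample=start))
    return epochs


def epoch_manifest(epochs: list[Epoch]) -> pd.DataFrame:
    """Tabulate epoch provenance (subject, channel, index, start_sample)."""
    return pd.DataFrame(
        [(e.subject_id, e.channel, e.index, e.start_sample) for e in epochs],
        columns=["subject_id", "channel", "index", "start_sample"],
    )
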
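"""Raw-recording conditioning: filtering, resampling, referencing, epoching.

A :class:`Recording` is the multichannel container every stage upstream of the
spectral analysis consumes: channels x samples in microvolts with a named
montage.  The conditioning chain mirrors a conventional resting-state qEEG
pipeline: zero-phase 0.5-70 Hz bandpass with a 50 Hz notch, downsampling to
256 Hz, average reference, and segmentation into non-overlapping 2 s windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from . import config


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "recorded"  # {"recorded", "average"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.reference not in ("recorded", "average"):
            raise ValueError(f"unknown reference state {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epochs:
    """Fixed-length non-overlapping windows cut from one recording.

    ``windows`` has shape (n_windows, n_channels, n_samples_per_window).
    """

    window_s: float
    windows: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, n_samples)")
        n_expected = self.window_s * self.fs
        if abs(n_expected - round(n_expected)) > 1e-9:
            raise ValueError("window length times sampling rate must be an integer")
        if self.windows.shape[2] != round(n_expected):
            raise ValueError("window sample count inconsistent with window_s * fs")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    def concatenate(self) -> np.ndarray:
        """Channels x samples array with windows re-joined in order."""
        return np.concatenate(list(self.windows), axis=1)


def bandpass_notch_downsample(
    rec: Recording,
    lo: float = 0.5,
    hi: float = 70.0,
    notch: float | None = 50.0,
    fs_out: float = config.FS,
) -> Recording:
    """Zero-phase bandpass + notch, then polyphase resampling to ``fs_out``.

    The bandpass is a 4th-order Butterworth (24 dB/oct rolloff) applied
    forward-backward, so the passband phase is untouched -- a requirement for
    any connectivity measure downstream.  The notch is a zero-phase IIR notch
    at the mains frequency.  Output length is ``floor(n * fs_out / fs)``.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if hi >= fs_out / 2:
        raise ValueError(f"upper edge {hi} Hz at or above Nyquist of fs_out={fs_out}")
    if hi >= rec.fs / 2:
        raise ValueError(f"upper edge {hi} Hz at or above Nyquist of fs={rec.fs}")

    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        b, a = signal.iirnotch(notch, Q=35.0, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)

    if fs_out != rec.fs:
        frac = Fraction(fs_out / rec.fs).limit_denominator(10_000)
        out = signal.resample_poly(out, frac.numerator, frac.denominator, axis=1)
        n_keep = int(np.floor(rec.n_samples * fs_out / rec.fs))
        out = out[:, :n_keep]
    return replace(rec, data=out, fs=fs_out)


def to_average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average; idempotent."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out, reference="average")


def segment(rec: Recording, window_s: float = config.WINDOW_S) -> Epochs:
    """Cut into consecutive non-overlapping windows, dropping the remainder."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win_samples = int(round(window_s * rec.fs))
    n_windows = rec.n_samples // n_win_samples
    if n_windows == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s shorter than one {window_s} s window"
        )
    trimmed = rec.data[:, : n_windows * n_win_samples]
    windows = trimmed.reshape(rec.n_channels, n_windows, n_win_samples)
    windows = np.moveaxis(windows, 1, 0)
    return Epochs(
        window_s=window_s,
        windows=windows.copy(),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def reject_windows(ep: Epochs, keep: np.ndarray) -> Epochs:
    """Artifact-rejection hook: keep windows flagged True in ``keep``.

    Manual or ICA-based cleaning is outside this pipeline (the synthetic data
    is clean); this pass-through lets an external cleaning step drop windows.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (ep.n_windows,):
        raise ValueError("keep mask must have one flag per window")
    if not keep.any():
        raise ValueError("mask removes every window")
    return Epochs(
        window_s=ep.window_s,
        windows=ep.windows[keep],
        fs=ep.fs,
        channel_labels=list(ep.channel_labels),
    )


def preprocess_recording(
    rec: Recording,
    lo: float = 0.5,
    hi: float = 70.0,
    notch: float | None = 50.0,
    fs_out: float = config.FS,
    window_s: float = config.WINDOW_S,
) -> Epochs:
    """Full conditioning chain: filter, downsample, average-reference, segment."""
    rec = bandpass_notch_downsample(rec, lo=lo, hi=hi, notch=notch, fs_out=fs_out)
    rec = to_average_reference(rec)
    return segment(rec, window_s=window_s)
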
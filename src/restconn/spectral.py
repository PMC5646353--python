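"""Power spectra, frequency bands and individual-alpha-frequency adjustment.

Spectra are window-averaged tapered periodograms on a 0.25 Hz grid.  Because
2 s windows natively give 0.5 Hz resolution, each window is zero-padded to 4 s
before the FFT; the 10% cosine (Tukey) taper is applied to the unpadded
window.  Band power is the mean PSD over the bins whose centers fall inside
the band, i.e. the integrated area divided by the band width in points.

The individual alpha frequency (IAF) is the channel-mean spectral peak in
7-13 Hz.  Band edges can be re-anchored to the IAF: every canonical edge e is
rescaled to (e / 10) * IAF, so an IAF of exactly 10 Hz reproduces the
canonical bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import config
from .preprocess import Epochs


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi, got ({self.lo}, {self.hi})")


#: Canonical bands in ascending order.
BANDS: dict[str, FrequencyBand] = {
    name: FrequencyBand(name, lo, hi) for name, (lo, hi) in config.CANONICAL_BANDS.items()
}

BAND_ORDER = tuple(BANDS)


@dataclass
class SpectrumSet:
    """Channel PSDs on a regular frequency grid (uV^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    n_windows: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.psd.ndim != 2 or self.psd.shape[1] != self.freqs.size:
            raise ValueError("psd must be channels x freqs")
        if (self.psd < 0).any():
            raise ValueError("psd must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def _taper_and_padding(n_win: int, fs: float) -> tuple[np.ndarray, int]:
    """Tukey taper for the raw window and the padded FFT length for the
    configured frequency resolution."""
    taper = signal.windows.tukey(n_win, alpha=config.TAPER_FRACTION)
    n_fft = int(round(fs / config.FREQ_RESOLUTION_HZ))
    n_fft = max(n_fft, n_win)
    return taper, n_fft


def window_fft(ep: Epochs) -> tuple[np.ndarray, np.ndarray, float]:
    """Tapered, zero-padded FFT of every window.

    Returns ``(freqs, X, scale)`` where ``X`` has shape
    (n_windows, n_channels, n_freqs) and ``scale * X * conj(X)`` is a
    one-sided PSD estimate (uV^2/Hz).
    """
    if ep.n_windows == 0:
        raise ValueError("no windows to transform")
    n_win = ep.windows.shape[2]
    taper, n_fft = _taper_and_padding(n_win, ep.fs)
    tapered = ep.windows * taper  # broadcast over trailing axis
    X = np.fft.rfft(tapered, n=n_fft, axis=2)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / ep.fs)
    # one-sided periodogram scaling with taper power normalization
    scale = 2.0 / (ep.fs * np.sum(taper**2))
    return freqs, X, scale


def power_spectrum(ep: Epochs) -> SpectrumSet:
    """Per-channel periodogram averaged across windows."""
    freqs, X, scale = window_fft(ep)
    psd = scale * (X.real**2 + X.imag**2)
    # DC and Nyquist bins carry no doubled negative-frequency twin
    psd[..., 0] /= 2.0
    if freqs[-1] == ep.fs / 2:
        psd[..., -1] /= 2.0
    return SpectrumSet(freqs=freqs, psd=psd.mean(axis=0), n_windows=ep.n_windows)


def band_bins(freqs: np.ndarray, band: FrequencyBand) -> np.ndarray:
    """Indices of the bins whose centers lie in [lo, hi], both ends closed."""
    mask = (freqs >= band.lo - 1e-12) & (freqs <= band.hi + 1e-12)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz outside frequency grid")
    return idx


def band_power(sp: SpectrumSet, band: FrequencyBand) -> np.ndarray:
    """Per-channel band power: mean PSD over in-band bins (uV^2 per point)."""
    if band.lo < sp.freqs[0] - 1e-12 or band.hi > sp.freqs[-1] + 1e-12:
        raise ValueError(f"band {band.name} extends beyond the frequency grid")
    idx = band_bins(sp.freqs, band)
    return sp.psd[:, idx].mean(axis=1)


def assign_band_bins(
    freqs: np.ndarray, bands: dict[str, FrequencyBand]
) -> dict[str, np.ndarray]:
    """Assign bins to bands; a bin on a shared edge goes to the lower band."""
    taken = np.zeros(freqs.size, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for name in sorted(bands, key=lambda n: bands[n].lo):
        idx = band_bins(freqs, bands[name])
        idx = idx[~taken[idx]]
        taken[idx] = True
        out[name] = idx
    return out


def estimate_iaf(sp: SpectrumSet, search_range: tuple[float, float] | None = None) -> float:
    """Individual alpha frequency: channel-mean PSD peak in the search range.

    Falls back to 10.0 Hz with a warning when the in-range spectrum is
    monotone (no local alpha peak to anchor on).
    """
    lo, hi = search_range or config.IAF_SEARCH_RANGE
    mean_psd = sp.psd.mean(axis=0)
    mask = (sp.freqs >= lo) & (sp.freqs <= hi)
    if not mask.any():
        raise ValueError("IAF search range outside frequency grid")
    seg = mean_psd[mask]
    fseg = sp.freqs[mask]
    diffs = np.diff(seg)
    monotone = (diffs >= -1e-300).all() or (diffs <= 1e-300).all()
    if monotone:
        warnings.warn(
            "no alpha peak in the search range; falling back to IAF = 10.0 Hz",
            stacklevel=2,
        )
        return 10.0
    return float(fseg[np.argmax(seg)])


def iaf_adjusted_bands(iaf: float, anchor_alpha: bool = True) -> dict[str, FrequencyBand]:
    """Rescale canonical band edges to an individual alpha frequency.

    Each canonical edge e (Hz) maps to ``(e / 10) * iaf``: e.g. IAF 10.1 Hz
    puts the delta band at 1.01-3.03 Hz.  Whether the alpha band itself is
    re-anchored is selectable (``anchor_alpha``); delta, theta and beta always
    are.  Gamma, lying above the range the rule was defined for, is kept
    canonical.
    """
    if not 7.0 <= iaf <= 13.0:
        raise ValueError(f"IAF {iaf} Hz outside the plausible 7-13 Hz range")
    adjusted: dict[str, FrequencyBand] = {}
    for name, band in BANDS.items():
        rescale = name in ("delta", "theta", "beta") or (name == "alpha" and anchor_alpha)
        if rescale:
            adjusted[name] = FrequencyBand(name, band.lo / 10.0 * iaf, band.hi / 10.0 * iaf)
        else:
            adjusted[name] = band
    return adjusted


def band_power_table(sp: SpectrumSet, bands: dict[str, FrequencyBand] | None = None):
    """Per-band, per-channel power as a {band: channel-array} dict."""
    bands = bands or BANDS
    return {name: band_power(sp, band) for name, band in bands.items()}
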
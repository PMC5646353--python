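"""Dynamic imaging of coherent sources (DICS): frequency-domain beamforming.

The band-limited linear structure of the sensor data is captured by the
cross-spectral density (CSD) matrix, averaged over windows and over the
band's frequency bins.  A linearly constrained minimum-variance spatial
filter built on the real part of the CSD maps power and coherence onto the
source grid: per voxel, weights minimize output power subject to unit gain at
the voxel, with the dipole orientation fixed to the dominant direction of the
voxel's 3x3 output-power matrix.

Coherent networks are found iteratively: the strongest-power voxel seeds the
search, the coherence map with respect to the current reference is
thresholded against a within-recording surrogate distribution (coherence
recomputed after shuffling one-second blocks of the reference time course,
which destroys the temporal pairing while preserving both spectra), and each
accepted source is claimed (suppressed) before the next pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import config
from .mvar import SourceSignals
from .preprocess import Epochs
from .forward import LeadField
from .spectral import FrequencyBand, band_bins, window_fft


@dataclass
class CSDMatrix:
    """Band-averaged complex cross-spectral density (channels x channels)."""

    band: FrequencyBand
    S: np.ndarray
    n_segments: int
    fs: float

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=complex)
        if not np.allclose(self.S, self.S.conj().T, atol=1e-10 * max(1.0, np.abs(self.S).max())):
            raise ValueError("CSD must be Hermitian")
        d = np.diagonal(self.S)
        if (d.real < -1e-12).any() or np.abs(d.imag).max(initial=0.0) > 1e-10 * max(1.0, d.real.max()):
            raise ValueError("CSD diagonal must be real and nonnegative")

    @property
    def n_channels(self) -> int:
        return self.S.shape[0]


def csd_matrix(ep: Epochs, band: FrequencyBand, min_segments: int = 8) -> CSDMatrix:
    """Segment- and band-averaged CSD with the spectral module's taper."""
    if ep.n_windows < min_segments:
        raise ValueError(f"need at least {min_segments} segments, got {ep.n_windows}")
    variances = ep.windows.var(axis=(0, 2))
    if (variances == 0).any():
        ch = int(np.argmax(variances == 0))
        name = ep.channel_labels[ch] if ep.channel_labels else str(ch)
        raise ValueError(f"channel {name!r} has zero variance")
    if ep.n_windows < ep.n_channels:
        warnings.warn(
            f"{ep.n_windows} segments for {ep.n_channels} channels: CSD is "
            "rank-deficient; regularization required downstream",
            stacklevel=2,
        )
    freqs, X, scale = window_fft(ep)
    idx = band_bins(freqs, band)
    Xb = X[:, :, idx]  # (win, ch, bins)
    S = scale * np.einsum("wcf,wdf->cd", Xb, Xb.conj()) / (ep.n_windows * idx.size)
    S = 0.5 * (S + S.conj().T)
    return CSDMatrix(band=band, S=S, n_segments=ep.n_windows, fs=ep.fs)


@dataclass
class SpatialFilter:
    """Per-voxel beamformer weights (n_vox x n_channels), fixed orientation."""

    band: FrequencyBand
    weights: np.ndarray
    orientations: np.ndarray
    lf: LeadField
    reg_frac: float

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


def dics_filter(
    csd: CSDMatrix, lf: LeadField, reg_frac: float = config.DICS_REG_FRAC
) -> SpatialFilter:
    """Unit-gain minimum-variance filter per voxel on the real CSD.

    The orientation at each voxel is the dominant eigenvector of the voxel
    output-power matrix (equivalently, the minimal eigenvector of
    L' C^-1 L); weights are w = C^-1 l / (l' C^-1 l) for the oriented gain l.
    """
    if reg_frac < 0:
        raise ValueError("reg_frac must be nonnegative")
    C = csd.S.real.copy()
    C += reg_frac * np.mean(np.diag(C)) * np.eye(C.shape[0])
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"regularized CSD is singular (cond={cond:.2e}); increase reg_frac"
        )
    Ci = np.linalg.inv(C)
    G = lf.gains  # (v, c, 3)
    K = np.einsum("vca,cd,vdb->vab", G, Ci, G)  # (v, 3, 3)
    evals, evecs = np.linalg.eigh(K)
    # minimal eigenvalue of K <-> dominant direction of the power matrix K^-1
    u = evecs[:, :, 0]
    l = np.einsum("vca,va->vc", G, u)  # oriented gains (v, c)
    Cil = l @ Ci.T
    denom = np.einsum("vc,vc->v", l, Cil)
    W = Cil / denom[:, None]
    config.log_choice("dics.reg_frac", reg_frac)
    return SpatialFilter(band=csd.band, weights=W, orientations=u, lf=lf, reg_frac=reg_frac)


def power_map(
    csd: CSDMatrix, filt: SpatialFilter, depth_normalize: bool = False
) -> np.ndarray:
    """Per-voxel band power through the filter.

    The default is plain unit-gain output power, which inflates deep voxels
    on noisy data (weights grow where lead fields are weak).  With
    ``depth_normalize`` the power is divided by the filter's noise gain
    ``w'w`` (the neural-activity-index convention), which removes that bias.
    """
    W = filt.weights
    p = np.einsum("vc,cd,vd->v", W, csd.S.real, W)
    if depth_normalize:
        p = p / np.einsum("vc,vc->v", W, W)
    return p


def coherence_map(csd: CSDMatrix, filt: SpatialFilter, ref_voxel: int) -> np.ndarray:
    """Magnitude-squared coherence of every voxel with the reference voxel.

    The value at the reference itself is 1 by construction.
    """
    if not 0 <= ref_voxel < filt.n_voxels:
        raise IndexError(f"reference voxel {ref_voxel} outside the grid")
    W = filt.weights
    p = power_map(csd, filt)
    w_ref = W[ref_voxel]
    cross = np.einsum("vc,cd,d->v", W, csd.S, w_ref)
    coh = np.abs(cross) ** 2 / (p * p[ref_voxel])
    return np.clip(coh, 0.0, None)


def _source_window_fft(ep: Epochs, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band-unrestricted window FFTs of beamformed time courses.

    Returns (freqs, Y) with Y of shape (n_vox_or_sources, n_windows, n_freqs).
    """
    freqs, X, _ = window_fft(ep)
    Y = np.einsum("vc,wcf->vwf", weights, X)
    return freqs, Y


def surrogate_threshold(
    ep: Epochs,
    band: FrequencyBand,
    filt: SpatialFilter,
    ref_voxel: int,
    n_perm: int = config.N_SURROGATE_PERM,
    seed: int | None = None,
    percentile: float = config.SURROGATE_PERCENTILE,
    voxels: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel surrogate coherence threshold.

    The reference source time course is re-paired against the unshifted voxel
    time courses by circular shifts of at least one second (a restricted
    shuffle of its one-second segments: the series stays spectrally
    contiguous except at the seam, so the null reproduces the observed
    estimator's bias exactly while the temporal pairing is destroyed).  The
    per-voxel threshold is the ``percentile`` of the ``n_perm`` null
    coherences, taken as the conservative (upper) order statistic.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    n_blocks = int(ep.n_windows * ep.window_s)
    if n_blocks < 20:
        raise ValueError(f"only {n_blocks} one-second blocks; need at least 20")
    rng = np.random.default_rng(seed)
    vox_idx = np.arange(filt.n_voxels) if voxels is None else np.asarray(voxels)
    W = filt.weights
    freqs, Yv = _source_window_fft(ep, W[vox_idx])
    idx = band_bins(freqs, band)
    Yv = Yv[:, :, idx]  # (v, w, f)
    p_vox = np.mean(np.abs(Yv) ** 2, axis=(1, 2))

    ref_course = np.einsum("c,wcs->ws", W[ref_voxel], ep.windows)  # (win, samp)
    n_win_samp = ref_course.shape[1]
    flat = ref_course.reshape(-1)
    block = int(round(ep.fs))

    from scipy.signal import windows as spwin

    taper = spwin.tukey(n_win_samp, alpha=config.TAPER_FRACTION)
    n_fft = int(round(ep.fs / config.FREQ_RESOLUTION_HZ))
    n_fft = max(n_fft, n_win_samp)

    null = np.empty((n_perm, vox_idx.size))
    for perm in range(n_perm):
        shift = int(rng.integers(block, flat.size - block))
        shuffled = np.roll(flat, shift)[: ep.n_windows * n_win_samp]
        swin = shuffled.reshape(ep.n_windows, n_win_samp) * taper
        Yr = np.fft.rfft(swin, n=n_fft, axis=1)[:, idx]  # (w, f)
        p_ref = np.mean(np.abs(Yr) ** 2)
        cross = np.mean(Yv * Yr.conj()[None, :, :], axis=(1, 2))
        null[perm] = np.abs(cross) ** 2 / (p_vox * p_ref)
    return np.percentile(null, percentile, axis=0, method="higher")


@dataclass
class SourceSet:
    """Ordered coherent sources of one band; the first is the power maximum."""

    band: FrequencyBand
    voxel_indices: list[int]
    positions: np.ndarray
    orientations: np.ndarray
    power: np.ndarray
    coherence_to_ref: np.ndarray
    surrogate_threshold: np.ndarray
    labels: list[str] = field(default_factory=list)
    flagged: bool = False

    @property
    def n_sources(self) -> int:
        return len(self.voxel_indices)


def find_coherent_sources(
    ep: Epochs,
    band: FrequencyBand,
    lf: LeadField,
    reg_frac: float = config.DICS_REG_FRAC,
    max_sources: int = config.MAX_SOURCES_PER_BAND,
    suppress_radius: float = config.SUPPRESSION_RADIUS_MM,
    n_perm: int = config.N_SURROGATE_PERM,
    seed: int | None = None,
    filt: SpatialFilter | None = None,
) -> SourceSet:
    """Iterative coherent-network identification for one band.

    The grand power maximum seeds the network; each pass thresholds the
    coherence map of the current reference against its surrogate level,
    accepts the strongest unclaimed suprathreshold voxel that is a *local
    maximum* of the map (beamformer leakage forms ridges around already-found
    sources; a genuine coherent source forms a peak), claims a neighborhood
    around it, and re-references to the newest source (falling back to
    earlier sources before giving up).  A seed with no coherent partner is
    returned alone and flagged.
    """
    csd = csd_matrix(ep, band)
    if filt is None:
        filt = dics_filter(csd, lf, reg_frac=reg_frac)
    pmap = power_map(csd, filt)
    # seed from the noise-normalized map: the raw unit-gain power maximum
    # drifts to deep voxels once several sources share the available SNR
    seed_vox = int(np.argmax(power_map(csd, filt, depth_normalize=True)))
    # two grid steps (10 mm on the production 5 mm grid): beamformer leakage
    # halos around a claimed source must not masquerade as new sources
    suppress = max(suppress_radius, 2.0 * lf.spacing)

    accepted = [seed_vox]
    coh_vals = [1.0]
    thr_vals = [np.nan]
    claimed = np.linalg.norm(lf.grid - lf.grid[seed_vox], axis=1) <= suppress
    rng = np.random.default_rng(seed)

    # neighbor lists for the local-maximum screen (26-connectivity)
    neigh_r = 1.8 * lf.spacing
    dists = np.linalg.norm(lf.grid[:, None, :] - lf.grid[None, :, :], axis=2)
    neighbors = [np.flatnonzero((dists[v] > 0) & (dists[v] <= neigh_r)) for v in range(lf.n_voxels)]

    def is_local_max(coh, v):
        nb = neighbors[v]
        return nb.size == 0 or (coh[v] >= coh[nb]).all()

    while len(accepted) < max_sources:
        found = False
        for ref in reversed(accepted):  # newest reference first
            coh = coherence_map(csd, filt, ref)
            thr = surrogate_threshold(
                ep, band, filt, ref, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            cand = np.flatnonzero(~claimed & (coh > thr))
            cand = np.array([v for v in cand if is_local_max(coh, v)], dtype=int)
            if cand.size:
                nxt = int(cand[np.argmax(coh[cand])])
                accepted.append(nxt)
                coh_vals.append(float(coh[nxt]))
                thr_vals.append(float(thr[nxt]))
                claimed |= np.linalg.norm(lf.grid - lf.grid[nxt], axis=1) <= suppress
                found = True
                break
        if not found:
            break

    flagged = len(accepted) == 1
    return SourceSet(
        band=band,
        voxel_indices=accepted,
        positions=lf.grid[accepted],
        orientations=filt.orientations[accepted],
        power=pmap[accepted],
        coherence_to_ref=np.array(coh_vals),
        surrogate_threshold=np.array(thr_vals),
        labels=[f"{band.name}_src{k + 1}" for k in range(len(accepted))],
        flagged=flagged,
    )


def extract_source_timecourses(
    ep: Epochs, srcs: SourceSet, filt: SpatialFilter
) -> SourceSignals:
    """Scalar time course per source: weights applied to the concatenated
    windows."""
    if any(v < 0 or v >= filt.n_voxels for v in srcs.voxel_indices):
        raise IndexError("source voxel outside the filter grid")
    data = filt.weights[srcs.voxel_indices] @ ep.concatenate()
    return SourceSignals(data=data, fs=ep.fs)
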
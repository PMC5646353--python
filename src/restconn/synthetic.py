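"""Ground-truth synthetic cohorts for the resting-state EEG pipeline.

No subject-level data is distributed with the study this pipeline emulates,
so every downstream stage is exercised on simulated cohorts with known truth:

* **Sources** are realizations of a stable MVAR system: optionally resonant
  (band-limited) self-dynamics per source plus explicit lagged couplings --
  the ground-truth analogue of the directed interactions RPDC estimates.
* **Scalp data** are the lead-field projection of those sources from chosen
  dipole positions, plus white sensor noise at a stated SNR.
* **Clinical covariates** follow the cohort's published group distributions:
  two groups of 17, PiB SUVR normal per group (HC 1.24 +- 0.2, MCI
  1.45 +- 0.2, positivity at >= 1.265), ApoE genotype frequencies per group,
  MMSE/CERAD/education summaries, and -- in the impaired group -- a negative
  rank association between SUVR and mean EEG connectivity, injected through a
  Gaussian copula on a latent connectivity factor that also scales the
  subject's MVAR coupling weights.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config
from .forward import LeadField, gain_at
from .mvar import SourceSignals, gaussian_innovations, simulate_mvar, spectral_radius
from .preprocess import Recording

# ---------------------------------------------------------------------------
# connectivity (source-level) specification


@dataclass
class ConnectivitySpec:
    """Ground-truth directed-coupling structure of the simulated sources.

    ``coupling`` lists (from_idx, to_idx, lag_samples, weight).  A source with
    a ``band_center_hz`` entry gets resonant AR(2) self-dynamics (pole radius
    ``resonance_r``) at that frequency; ``None`` leaves it white.
    """

    n_sources: int
    coupling: list[tuple[int, int, int, float]] = field(default_factory=list)
    band_center_hz: float | list[float | None] | None = None
    noise_sd: float = 1.0
    resonance_r: float = 0.95

    def __post_init__(self) -> None:
        for frm, to, lag, _w in self.coupling:
            if frm == to:
                raise ValueError("self-coupling listed in coupling table")
            if not (0 <= frm < self.n_sources and 0 <= to < self.n_sources):
                raise ValueError("coupling index outside the source set")
            if lag < 1:
                raise ValueError("coupling lag must be >= 1 sample")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def band_centers(self) -> list[float | None]:
        if self.band_center_hz is None:
            return [None] * self.n_sources
        if np.isscalar(self.band_center_hz):
            return [float(self.band_center_hz)] * self.n_sources
        return list(self.band_center_hz)


def coefficient_matrices(
    spec: ConnectivitySpec, fs: float, weight_scale: float = 1.0
) -> np.ndarray:
    """Build the (p, m, m) MVAR coefficient stack implied by the spec."""
    m = spec.n_sources
    lags = [lag for _, _, lag, _ in spec.coupling]
    centers = spec.band_centers()
    p = max([2 if any(c is not None for c in centers) else 1] + lags) if (lags or any(c is not None for c in centers)) else 1
    A = np.zeros((p, m, m))
    for s, f0 in enumerate(centers):
        if f0 is not None:
            theta = 2.0 * np.pi * f0 / fs
            r = spec.resonance_r
            A[0, s, s] = 2.0 * r * np.cos(theta)
            A[1, s, s] = -(r**2)
    for frm, to, lag, w in spec.coupling:
        A[lag - 1, to, frm] += w * weight_scale
    return A


def simulate_mvar_sources(
    spec: ConnectivitySpec,
    n_samples: int,
    fs: float = config.FS,
    seed: int | None = None,
    weight_scale: float = 1.0,
) -> SourceSignals:
    """Simulate the specified MVAR system with Gaussian innovations."""
    A = coefficient_matrices(spec, fs, weight_scale=weight_scale)
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(
            f"unstable connectivity spec: companion spectral radius {rho:.3f} >= 1"
        )
    max_lag = A.shape[0]
    if n_samples <= 10 * max_lag:
        raise ValueError(f"n_samples={n_samples} too short for max lag {max_lag}")
    rng = np.random.default_rng(seed)
    Sigma = spec.noise_sd**2 * np.eye(spec.n_sources)
    innov = gaussian_innovations(rng, Sigma, n_samples + 10 * max_lag)
    burn = 10 * max_lag
    data = simulate_mvar(A, innov, burn_in=burn)
    return SourceSignals(data=data, fs=fs)


# ---------------------------------------------------------------------------
# scalp projection


def project_to_scalp(
    sources: SourceSignals,
    dipole_positions: np.ndarray,
    dipole_orientations: np.ndarray,
    lf: LeadField,
    sensor_noise_snr: float = 10.0,
    seed: int | None = None,
    source_scale: float = 50.0,
) -> Recording:
    """Project source time courses through the forward model to the scalp.

    ``sensor_noise_snr`` is in dB (``np.inf`` for noise-free); SNR is defined
    against the mean channel power of the projected signal, so silent sources
    with finite SNR are rejected.  ``source_scale`` sets the microvolt scale
    of the projection (unit-variance sources map to roughly this many uV of
    scalp signal at the strongest channels).
    """
    dipole_positions = np.atleast_2d(np.asarray(dipole_positions, float))
    dipole_orientations = np.atleast_2d(np.asarray(dipole_orientations, float))
    if len(dipole_positions) != sources.n_sources:
        raise ValueError("one dipole position per source required")
    hm = lf.head_model
    for k, pos in enumerate(dipole_positions):
        if np.linalg.norm(pos) >= hm.inner_radius:
            raise ValueError(
                f"dipole {k} at radius {np.linalg.norm(pos):.1f} mm lies outside "
                f"the innermost shell ({hm.inner_radius:.1f} mm)"
            )
    norms = np.linalg.norm(dipole_orientations, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("dipole orientations must be unit-norm")

    gains = np.stack(
        [gain_at(lf, pos, ori) for pos, ori in zip(dipole_positions, dipole_orientations)]
    )  # (k, channels)
    # normalize the gain scale so source_scale has uV meaning
    gmax = np.abs(gains).max()
    if gmax > 0:
        gains = gains / gmax * source_scale
    scalp = gains.T @ sources.data  # (channels, samples)
    signal_power = float(np.mean(scalp**2))
    if np.isfinite(sensor_noise_snr):
        if signal_power == 0.0:
            raise ValueError("SNR undefined for silent sources")
        noise_var = signal_power / 10.0 ** (sensor_noise_snr / 10.0)
        rng = np.random.default_rng(seed)
        scalp = scalp + rng.normal(scale=np.sqrt(noise_var), size=scalp.shape)
    scalp = scalp - scalp.mean(axis=0, keepdims=True)
    return Recording(
        channel_labels=list(lf.channel_labels),
        fs=sources.fs,
        data=scalp,
        reference="average",
    )


# ---------------------------------------------------------------------------
# cohort generation

#: Default ApoE genotype frequencies.  MCI follows the published genotype
#: counts (1 E2/E3, 11 E3/E3, 4 E3/E4, 1 E4/E4 of 17); HC is dichotomous
#: (13 E3/E3, 4 E3/E4 of 17, i.e. 4 carriers).
APOE_FREQS: dict[str, dict[str, float]] = {
    "HC": {"E3/E3": 13 / 17, "E3/E4": 4 / 17},
    "MCI": {"E2/E3": 1 / 17, "E3/E3": 11 / 17, "E3/E4": 4 / 17, "E4/E4": 1 / 17},
}

APOE_ORDINAL = {"E2/E3": 0, "E3/E3": 1, "E3/E4": 2, "E4/E4": 3}

#: Per-group demographic and clinical distributions (mean, sd).
DEMOGRAPHICS = {
    "HC": {"age": (71.8, 4.6), "mmse": (29.65, 0.6), "cerad_z": (0.75, 1.2), "education": (15.35, 2.7)},
    "MCI": {"age": (72.1, 4.6), "mmse": (28.41, 1.4), "cerad_z": (-0.95, 1.1), "education": (14.76, 2.9)},
}

#: Fraction of males in each group (13 of 18 reported slots).
MALE_FRACTION = 13 / 18

#: Per-band EEG summary distributions (HC mean, MCI mean, sd).  The alpha and
#: beta bands carry the group effects; the remaining bands are matched across
#: groups.  Values sit in the range group-level summaries of this kind take
#: for coherence, log source power and display-scale RPDC.
EEG_SUMMARY_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "coherence": {
        "delta": (0.21, 0.21, 0.03),
        "theta": (0.18, 0.18, 0.03),
        "alpha": (0.19, 0.14, 0.03),
        "beta": (0.17, 0.13, 0.025),
        "gamma": (0.10, 0.10, 0.02),
    },
    "power": {
        "delta": (1.27, 1.27, 0.05),
        "theta": (1.15, 1.15, 0.05),
        "alpha": (1.37, 0.98, 0.065),
        "beta": (1.52, 0.89, 0.13),
        "gamma": (0.91, 0.91, 0.14),
    },
    "rpdc": {
        "delta": (0.18, 0.18, 0.03),
        "theta": (0.16, 0.16, 0.035),
        "alpha": (0.21, 0.15, 0.025),
        "beta": (0.25, 0.19, 0.025),
        "gamma": (0.13, 0.13, 0.025),
    },
}

#: Band-by-measure cells that truly differ between groups under the defaults.
EFFECT_CELLS = tuple(
    (measure, band)
    for measure, bands in EEG_SUMMARY_PARAMS.items()
    for band, (hc, mci, _sd) in bands.items()
    if hc != mci
)

#: Share of each EEG summary's variance carried by the subject-level latent
#: connectivity factor (the remainder is band-specific).
LATENT_WEIGHT2 = 0.5


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic two-group cohort."""

    n_per_group: int = 17
    suvr_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (1.24, 0.2), "MCI": (1.45, 0.2)}
    )
    apoe_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in APOE_FREQS.items()}
    )
    suvr_connectivity_r: float = -0.8
    seed: int = 0
    suvr_cutoff: float = config.SUVR_POSITIVITY_CUTOFF

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for group, freqs in self.apoe_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"ApoE frequencies for {group} sum to {total}, not 1")
        if not -1.0 < self.suvr_connectivity_r < 1.0:
            raise ValueError("suvr_connectivity_r must be in (-1, 1)")


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula latent correlation reproducing a Spearman target."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _latent_correlation(target_spearman: float) -> float:
    """Latent SUVR-factor correlation, pre-compensated for the dilution the
    band-specific noise introduces into the mean-connectivity composite."""
    sds = [
        params[band][2]
        for measure, params in EEG_SUMMARY_PARAMS.items()
        if measure in ("coherence", "rpdc")
        for band in params
    ]
    s1 = sum(sds)
    s2 = sum(s * s for s in sds)
    w = np.sqrt(LATENT_WEIGHT2)
    atten = w * s1 / np.sqrt(LATENT_WEIGHT2 * s1 * s1 + (1 - LATENT_WEIGHT2) * s2)
    rho = _spearman_to_pearson(target_spearman) / atten
    return float(np.clip(rho, -0.999, 0.999))


def simulate_cohort(
    cspec: CohortSpec,
    conn_effect: dict[str, ConnectivitySpec] | None = None,
    recording_cfg: dict | None = None,
) -> tuple[pd.DataFrame, list[Recording | None]]:
    """Draw a two-group cohort table and (optionally) per-subject recordings.

    The table carries demographics, SUVR, ApoE codings, the amyloid flag and
    per-band EEG summary measures (power, coherence, RPDC).  In the MCI group
    a latent connectivity factor is copula-coupled to SUVR so the realized
    Spearman correlation between SUVR and mean connectivity matches
    ``cspec.suvr_connectivity_r``; the same factor scales the MVAR coupling
    weights of the subject's simulated recording.

    ``recording_cfg`` keys: ``lead_field`` (required for recordings),
    ``duration_s`` (default 240), ``snr_db`` (default 10),
    ``dipole_positions``/``dipole_orientations``, and ``n_recordings_per_group``
    to cap how many subjects get full recordings (default 0: table only).
    """
    rng = np.random.default_rng(cspec.seed)
    rho_latent = _latent_correlation(cspec.suvr_connectivity_r)
    w = np.sqrt(LATENT_WEIGHT2)

    rows = []
    latent_factors: list[float] = []
    for group in ("HC", "MCI"):
        mu, sd = cspec.suvr_params[group]
        demo = DEMOGRAPHICS[group]
        genos = list(cspec.apoe_freqs[group])
        probs = np.array([cspec.apoe_freqs[group][g] for g in genos])
        z_suvr = rng.standard_normal(cspec.n_per_group)
        suvr = mu + sd * z_suvr
        if group == "MCI":
            z_conn = rho_latent * z_suvr + np.sqrt(1 - rho_latent**2) * rng.standard_normal(
                cspec.n_per_group
            )
        else:
            z_conn = rng.standard_normal(cspec.n_per_group)
        for s in range(cspec.n_per_group):
            row = {
                "subject_id": f"{group}{s + 1:02d}",
                "group": group,
                "age": rng.normal(*demo["age"]),
                "sex": "M" if rng.random() < MALE_FRACTION else "F",
                "education": rng.normal(*demo["education"]),
                "mmse": float(np.clip(rng.normal(*demo["mmse"]), 0, 30)),
                "cerad_z": rng.normal(*demo["cerad_z"]),
                "suvr": float(suvr[s]),
                "amyloid_positive": bool(suvr[s] >= cspec.suvr_cutoff),
            }
            geno = genos[rng.choice(len(genos), p=probs)]
            row["apoe"] = geno
            row["apoe_ordinal"] = APOE_ORDINAL[geno]
            row["e4_carrier"] = "E4" in geno
            conn_vals = []
            for measure, bands in EEG_SUMMARY_PARAMS.items():
                for band, (hc_mean, mci_mean, bsd) in bands.items():
                    mean = hc_mean if group == "HC" else mci_mean
                    eps = rng.standard_normal()
                    val = mean + bsd * (w * z_conn[s] + np.sqrt(1 - w**2) * eps)
                    if measure in ("coherence", "rpdc"):
                        val = float(np.clip(val, 1e-4, 0.999))
                        conn_vals.append(val)
                    row[f"{measure}_{band}"] = float(val)
            row["conn_mean"] = float(np.mean(conn_vals))
            row["conn_latent"] = float(z_conn[s])
            rows.append(row)
            latent_factors.append(float(z_conn[s]))

    table = pd.DataFrame(rows)

    recordings: list[Recording | None] = [None] * len(table)
    cfg = recording_cfg or {}
    n_rec = int(cfg.get("n_recordings_per_group", 0))
    if n_rec > 0:
        lf = cfg.get("lead_field")
        if lf is None:
            raise ValueError("recording_cfg must include a lead_field to make recordings")
        duration = float(cfg.get("duration_s", 240.0))
        snr_db = float(cfg.get("snr_db", 10.0))
        fs = float(cfg.get("fs", config.FS))
        # default ground truth: an alpha-oscillator driver feeding a chain at
        # a quarter-period lag -- high within-band coherence, low zero-lag
        # correlation (the regime the beamformer assumes) -- with weaker
        # information flow in the impaired group
        conn_effect = conn_effect or {
            "HC": ConnectivitySpec(
                n_sources=3,
                coupling=[(0, 1, 6, 0.7), (1, 2, 6, 0.7)],
                band_center_hz=[10.0, None, None],
            ),
            "MCI": ConnectivitySpec(
                n_sources=3,
                coupling=[(0, 1, 6, 0.45), (1, 2, 6, 0.45)],
                band_center_hz=[10.0, None, None],
            ),
        }
        default_pos = np.array([[0.0, 40.0, 30.0], [-35.0, -25.0, 25.0], [35.0, -25.0, 25.0]])
        default_ori = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        dip_pos = np.asarray(cfg.get("dipole_positions", default_pos), float)
        dip_ori = np.asarray(cfg.get("dipole_orientations", default_ori), float)
        n_samples = int(round(duration * fs))
        for gi, group in enumerate(("HC", "MCI")):
            spec_g = conn_effect[group]
            for s in range(min(n_rec, cspec.n_per_group)):
                idx = gi * cspec.n_per_group + s
                # SUVR-linked attenuation of coupling in the impaired group
                scale = float(np.exp(0.2 * latent_factors[idx])) if group == "MCI" else 1.0
                sub_seed = int(rng.integers(2**31 - 1))
                src = simulate_mvar_sources(
                    spec_g, n_samples, fs=fs, seed=sub_seed, weight_scale=scale
                )
                recordings[idx] = project_to_scalp(
                    src,
                    dip_pos[: spec_g.n_sources],
                    dip_ori[: spec_g.n_sources],
                    lf,
                    sensor_noise_snr=snr_db,
                    seed=sub_seed + 1,
                )
    return table, recordings
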
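"""Central defaults for the resting-state EEG connectivity pipeline.

Every tunable the pipeline uses lives here so that analysis drivers and tests
share one set of study conditions.  Values the source-analysis literature fixes
by convention (band edges, the 0.25 Hz grid, the 5 mm voxel size) are treated
as part of the method; values it does not fix (shell radii, conductivities,
regularization) are documented choices.
"""

from __future__ import annotations

import logging

log = logging.getLogger("restconn")

#: Canonical frequency bands (Hz): delta, theta, alpha, beta, gamma.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 49.0),
}

#: Target spectral resolution of the FFT grid (Hz).
FREQ_RESOLUTION_HZ = 0.25

#: Epoch length used throughout (seconds) and working sampling rate (Hz).
WINDOW_S = 2.0
FS = 256.0

#: Fraction of each window covered by the cosine taper (Tukey window).  The
#: analyzer-software convention "Hanning window: 10%" means a 10% taper, not a
#: full Hann window.
TAPER_FRACTION = 0.10

#: IAF search range (Hz).
IAF_SEARCH_RANGE = (7.0, 13.0)

#: Five-shell head model, inside out: white matter, gray matter, CSF, skull,
#: skin.  Radii in mm (88 mm scalp sphere), conductivities in S/m.  The shell
#: geometry follows standard published multishell values; it is a volume
#: conductor convention, not a fitted quantity.
HEAD_RADII_MM = (67.0, 71.0, 74.0, 81.0, 88.0)
HEAD_CONDUCTIVITIES = (0.14, 0.33, 1.79, 0.01, 0.43)

#: Source-grid spacing (mm) for production tomographies; tests use coarser
#: grids for speed.
GRID_SPACING_MM = 5.0

#: Diagonal loading of the real CSD in the beamformer, as a fraction of the
#: mean sensor power.
DICS_REG_FRAC = 0.05

#: Iterative coherent-source search: cap on sources per band and suppression
#: radius (mm) around claimed voxels.
MAX_SOURCES_PER_BAND = 5
SUPPRESSION_RADIUS_MM = 10.0

#: Surrogate significance: permutations and null percentile.
N_SURROGATE_PERM = 100
SURROGATE_PERCENTILE = 99.0

#: MVAR / RPDC defaults.
MVAR_MAX_ORDER = 20
N_BOOTSTRAP = 100
BOOTSTRAP_PERCENTILE = 95.0

#: Amyloid positivity cutoff (SUVR, cortical PiB relative to cerebellar gray).
SUVR_POSITIVITY_CUTOFF = 1.265

#: SVM capacity grid (log-spaced 1..1000) and polynomial-kernel settings.
SVM_C_GRID = (1.0, 3.16, 10.0, 31.6, 100.0, 316.0, 1000.0)
SVM_GAMMA = 0.25
SVM_POLY_DEGREE = 3

#: BEST-style Bayesian estimation: MCMC sampling steps.
BEST_N_STEPS = 100_000

#: Multiplicity family sizes mirroring the analysis plan: 15 for the
#: band-by-measure group battery, 30 for clinical interactions, 36 for
#: cognition.
BONFERRONI_M_BATTERY = 15
BOOTSTRAP_M_CLINICAL = 30
BOOTSTRAP_M_COGNITION = 36


def log_choice(name: str, value) -> None:
    """Log a configurable choice at INFO level so every run records it."""
    log.info("config: %s = %r", name, value)
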
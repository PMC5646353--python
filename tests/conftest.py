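"""Shared fixtures: a coarse lead field and canonical synthetic recordings.

Everything is generated programmatically; grids are coarser and recordings
shorter than production settings so the suite stays fast, with sizes chosen
so every statistical check keeps its planned power.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import restconn as rc
from restconn import montage, synthetic

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def head_model():
    return rc.build_head_model()


@pytest.fixture(scope="session")
def coarse_lead_field(head_model):
    """15 mm source grid on the default head model (217 voxels, 60 channels)."""
    epos = montage.standard_positions(scalp_radius_mm=head_model.scalp_radius)
    return rc.compute_lead_field(
        head_model, epos, list(montage.CHANNELS_60), grid_spacing=15.0
    )


@pytest.fixture(scope="session")
def alpha_band():
    return rc.BANDS["alpha"]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_noise_recording(n_channels=4, seconds=30.0, fs=256.0, seed=0):
    r = np.random.default_rng(seed)
    return rc.Recording(
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        fs=fs,
        data=r.standard_normal((n_channels, int(seconds * fs))),
    )


def single_dipole_recording(lf, voxel, seconds=30.0, snr_db=10.0, seed=0, f0=10.0):
    """Band-limited dipole at a grid node projected to the scalp."""
    spec = synthetic.ConnectivitySpec(n_sources=1, band_center_hz=f0)
    src = synthetic.simulate_mvar_sources(
        spec, int(seconds * 256), fs=256.0, seed=seed
    )
    return synthetic.project_to_scalp(
        src, lf.grid[voxel], [[0.0, 0.0, 1.0]], lf, sensor_noise_snr=snr_db,
        seed=seed + 1,
    ), src
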
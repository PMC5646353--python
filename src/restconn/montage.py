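"""Standard electrode template for the 60-channel 10-20/10-10 montage."""

from __future__ import annotations

import warnings

import numpy as np

#: The 60 scalp labels of the recording montage (10-20 plus 10-10 positions).
CHANNELS_60: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Iz", "Cz", "Pz", "FC1",
    "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "TP9", "TP10", "Fpz",
    "Oz", "FT9", "FT10", "PO9", "PO10", "C1", "C2", "PO1", "PO2", "Fz",
    "AFz", "F5", "F6", "FT7", "FT8", "FC3", "FC4", "C5", "C6", "TP7",
    "TP8", "CP3", "CP4", "P5", "P6", "OI1", "OI2", "FCz", "CPz", "POz",
)


def standard_positions(
    labels: tuple[str, ...] = CHANNELS_60, scalp_radius_mm: float = 88.0
) -> np.ndarray:
    """Template positions (n, 3) in mm, radially projected to a scalp sphere.

    Positions come from the installed standard 10-05 montage template and are
    re-centered on the sphere origin before projection, so they are exact
    spherical coordinates suited to the concentric-sphere conductor.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except Exception:  # template renamed in newer releases
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos_map = mont.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos_map]
    if missing:
        raise KeyError(f"labels missing from the standard template: {missing}")
    xyz = np.array([pos_map[l] for l in labels]) * 1000.0  # m -> mm
    xyz -= xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])  # center laterally
    # drop below-origin offset so the cap sits on the upper hemisphere
    r = np.linalg.norm(xyz, axis=1)
    return xyz * (scalp_radius_mm / r)[:, None]
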
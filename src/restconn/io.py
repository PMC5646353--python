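"""Recording and cohort-table I/O.

Recordings round-trip through the BrainVision triplet (.vhdr/.vmrk text
headers plus IEEE float32 multiplexed .eeg) written natively here, and are
read back -- like EDF files -- through the installed MNE readers.  Cohort
tables are plain CSV with a documented column dictionary.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording

#: Column dictionary of the cohort CSV (kept next to the writer so the file
#: format and its documentation cannot drift apart).
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "group": "cohort label: HC (healthy control) or MCI",
    "age": "age in years",
    "sex": "M or F",
    "education": "education in years",
    "mmse": "Mini-Mental State Examination score (0-30)",
    "cerad_z": "CERAD delayed-recall z-score",
    "suvr": "cortical PiB SUVR (amyloid burden vs cerebellar gray)",
    "amyloid_positive": "SUVR >= 1.265 positivity flag",
    "apoe": "ApoE genotype string, e.g. E3/E4",
    "apoe_ordinal": "genetic-risk rank: E2/E3 < E3/E3 < E3/E4 < E4/E4",
    "e4_carrier": "carries at least one epsilon-4 allele",
    "power_<band>": "per-band mean source log power",
    "coherence_<band>": "per-band mean source coherence (0-1)",
    "rpdc_<band>": "per-band mean directed coherence, display scale (0-1)",
    "conn_mean": "mean of the coherence and RPDC summaries across bands",
    "conn_latent": "latent connectivity factor used by the generator",
}


def write_brainvision(rec: Recording, vhdr_path: str | Path) -> Path:
    """Write a Recording as a BrainVision triplet; returns the .vhdr path."""
    vhdr = Path(vhdr_path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("path must end in .vhdr")
    stem = vhdr.with_suffix("")
    eeg, vmrk = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")

    interval_us = 1e6 / rec.fs
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk.write_text(
        "BrainVision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_recording(path: str | Path, reference: str = "recorded") -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into a Recording."""
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif path.suffix in (".edf", ".EDF"):
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported recording format {path.suffix!r}")
    data_uv = raw.get_data() * 1e6  # MNE works in volts
    return Recording(
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        reference=reference,
    )


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"subject_id", "group", "suvr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return table
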
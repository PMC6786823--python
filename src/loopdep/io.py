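"""Tabular I/O: BIDS-style events TSV files and serializable configs.

Events files are tab-separated with a header row; onsets are in seconds and
trial intervals are half-open ``[onset, onset + duration)``.  Missing values
are written as ``n/a`` per the BIDS convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

REQUIRED_SCHEDULE_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "block",
    "event_id",
    "loop_type",
    "cue_id",
    "target_id",
    "lure1",
    "lure2",
    "lure3",
)


def write_events_tsv(records: pd.DataFrame, path) -> None:
    """Write a trial table as a tab-separated events file."""
    records.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path, required: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read a tab-separated events file into a DataFrame.

    Raises a descriptive error when a required column is missing or a row is
    malformed (pandas reports the offending line number).  An empty file
    yields an empty DataFrame with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning no records")
        return pd.DataFrame()
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed events file {path}: {err}") from err
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path} missing required column(s): {missing}")
    return df


def write_volume(data, path, affine=None) -> None:
    """Write a 3-D/4-D array as a NIfTI volume (identity affine by default)."""
    import nibabel as nib
    import numpy as np

    img = nib.Nifti1Image(
        np.asarray(data, dtype=np.float64),
        np.eye(4) if affine is None else affine,
    )
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return img.get_fdata(), img.affine


def read_outcomes_tsv(path, mode: str = "accuracy") -> pd.DataFrame:
    """Read a trial-outcome table, validating the analysis-mode columns."""
    required = ["participant_id", "event_id", "loop_type", "cue_id", "target_id", "correct"]
    if mode == "confidence":
        required.append("confidence")
    return read_events_tsv(path, tuple(required))
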
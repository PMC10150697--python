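"""Paired reference/estimate series shared by all agreement statistics.

A "paired series" is a DataFrame with columns ``subject_id``,
``epoch_start`` (s), ``reference`` and ``estimate`` (mmHg), one row per
epoch.  Errors are always ``estimate - reference``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import InsufficientDataError

PAIR_COLUMNS = ("subject_id", "epoch_start", "reference", "estimate")


def make_pairs(subject_id, epoch_start, reference, estimate) -> pd.DataFrame:
    df = pd.DataFrame({
        "subject_id": subject_id, "epoch_start": epoch_start,
        "reference": np.asarray(reference, float),
        "estimate": np.asarray(estimate, float),
    })
    return check_pairs(df)


def check_pairs(pairs: pd.DataFrame, min_rows: int = 1) -> pd.DataFrame:
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise InsufficientDataError(f"paired series lacks columns {missing}")
    if len(pairs) < min_rows:
        raise InsufficientDataError(f"paired series needs >= {min_rows} rows")
    if pairs[["reference", "estimate"]].isna().any().any():
        raise InsufficientDataError("paired series must not contain missing values")
    return pairs


def errors(pairs: pd.DataFrame) -> np.ndarray:
    return pairs["estimate"].to_numpy(float) - pairs["reference"].to_numpy(float)


def sort_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Subject-major, time-minor order (required by DM/ADF)."""
    return pairs.sort_values(["subject_id", "epoch_start"], kind="mergesort").reset_index(drop=True)
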
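"""15-s epoch aggregation and the train/test split.

Epoch grid is anchored at the subject's first valid beat; intervals are
half-open [start, start + epoch_s).  Epoch values are means over *valid*
beats only; epochs with too few valid beats are dropped.  The split assigns
the first half of surviving epochs (by time) to ``train`` and the rest to
``test``, mirroring a first-half-train / second-half-test protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import InvalidRecordError
from .beats import BeatSeries

DEFAULT_EPOCH_S = 15.0
DEFAULT_MIN_BEATS = 5

EPOCH_BASE_COLUMNS = (
    "subject_id", "epoch_start", "ref_sbp", "ref_dbp", "ref_map",
    "pat", "hr", "n_valid_beats", "split",
)


def aggregate_epochs(
    beats: BeatSeries,
    epoch_s: float = DEFAULT_EPOCH_S,
    min_beats: int = DEFAULT_MIN_BEATS,
    *,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Average a BeatSeries into non-overlapping epochs.

    Returns a table with reference BP (``ref_sbp``/``ref_dbp``/``ref_map``),
    cuffless features (``pat``, ``hr`` and any attached PPG morphology
    columns), ``n_valid_beats`` and the ``split`` label.
    """
    if epoch_s <= 0:
        raise InvalidRecordError("epoch_s must be positive")
    if np.any(np.diff(beats.r_time) <= 0):
        raise InvalidRecordError("beats must be time-sorted")
    valid = beats.valid
    if valid.sum() == 0:
        return pd.DataFrame(columns=list(EPOCH_BASE_COLUMNS))

    df = beats.to_frame()[valid].copy()
    t0 = float(df["r_time"].iloc[0])
    df["_epoch"] = np.floor((df["r_time"] - t0) / epoch_s).astype(int)

    value_cols = ["sbp", "dbp", "map", "pat", "hr"]
    feature_cols = [] if beats.features is None else [
        c for c in beats.features.columns if c not in ("pat", "hr")
    ]
    agg = df.groupby("_epoch")[value_cols + feature_cols].mean()
    agg["n_valid_beats"] = df.groupby("_epoch").size()
    agg = agg[agg["n_valid_beats"] >= min_beats]

    out = pd.DataFrame({
        "subject_id": subject_id,
        "epoch_start": t0 + agg.index.to_numpy() * epoch_s,
        "ref_sbp": agg["sbp"].to_numpy(),
        "ref_dbp": agg["dbp"].to_numpy(),
        "ref_map": agg["map"].to_numpy(),
        "pat": agg["pat"].to_numpy(),
        "hr": agg["hr"].to_numpy(),
    })
    for c in feature_cols:
        out[c] = agg[c].to_numpy()
    out["n_valid_beats"] = agg["n_valid_beats"].to_numpy()
    out = out.sort_values("epoch_start").reset_index(drop=True)
    out["split"] = assign_split(len(out))
    return out


def assign_split(n_epochs: int) -> np.ndarray:
    """First half (by time) train, second half test; |n_train-n_test| <= 1."""
    n_train = (n_epochs + 1) // 2
    return np.array(["train"] * n_train + ["test"] * (n_epochs - n_train), dtype=object)
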
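"""Subject-level inclusion criteria.

A subject enters the analysis only if
(1) the ratio of valid device beats to reference beats is at least 0.6,
(2) the recording yields at least 200 reference/cuffless epoch pairs, and
(3) the SD of reference SBP over the first half of the data is at least 50%
    of the SD over the whole recording (enough BP variation for training a
    subject-specific model).

Criterion (3) is computed on SBP by default (configurable to MAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import InsufficientDataError
from .beats import BeatSeries

F_LOW_VALID_RATIO = "low_valid_ratio"
F_SHORT_RECORDING = "short_recording"
F_LOW_TRAIN_VARIATION = "low_train_variation"

DEFAULT_MIN_VALID_RATIO = 0.6
DEFAULT_MIN_PAIRS = 200
DEFAULT_MIN_SD_RATIO = 0.5


@dataclass
class QCReport:
    subject_id: str
    valid_ratio: float
    n_pairs: int
    sd_first_half: float
    sd_total: float
    included: bool
    failed_criteria: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "valid_ratio": round(self.valid_ratio, 4),
            "n_pairs": self.n_pairs,
            "sd_first_half": round(self.sd_first_half, 3),
            "sd_total": round(self.sd_total, 3),
            "included": self.included,
            "failed_criteria": list(self.failed_criteria),
        }


def qc_subject(
    epochs: pd.DataFrame,
    beats: BeatSeries,
    *,
    min_valid_ratio: float = DEFAULT_MIN_VALID_RATIO,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_sd_ratio: float = DEFAULT_MIN_SD_RATIO,
    sd_component: str = "ref_sbp",
) -> QCReport:
    """Apply the three subject-exclusion criteria; included iff none fail."""
    if len(epochs) == 0:
        raise InsufficientDataError("epoch table is empty")
    subject_id = str(epochs["subject_id"].iloc[0])

    valid_ratio = float(np.mean(beats.valid)) if len(beats) else 0.0
    n_pairs = int(len(epochs))
    if "split" in epochs.columns:
        first = epochs[epochs["split"] == "train"][sd_component]
    else:
        first = epochs[sd_component].iloc[: (len(epochs) + 1) // 2]
    sd_first = float(first.std(ddof=1)) if len(first) > 1 else 0.0
    sd_total = float(epochs[sd_component].std(ddof=1)) if n_pairs > 1 else 0.0

    failed = []
    if valid_ratio < min_valid_ratio:
        failed.append(F_LOW_VALID_RATIO)
    if n_pairs < min_pairs:
        failed.append(F_SHORT_RECORDING)
    if sd_total > 0 and sd_first < min_sd_ratio * sd_total:
        failed.append(F_LOW_TRAIN_VARIATION)
    return QCReport(
        subject_id=subject_id, valid_ratio=valid_ratio, n_pairs=n_pairs,
        sd_first_half=sd_first, sd_total=sd_total,
        included=not failed, failed_criteria=failed,
    )
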
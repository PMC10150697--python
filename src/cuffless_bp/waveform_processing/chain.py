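"""Full processing chain: raw record -> QC'd epoch table."""

from __future__ import annotations

import pandas as pd

from ..bp_models.features import beat_morphology
from ..synthetic_cohort.waveforms import SubjectRecord
from .beats import BeatSeries, compute_pat_hr, extract_beat_bp, filter_arterial_artifacts
from .epochs import DEFAULT_EPOCH_S, DEFAULT_MIN_BEATS, aggregate_epochs
from .fiducials import detect_ppg_feet, detect_r_peaks


def process_record(
    rec: SubjectRecord,
    *,
    epoch_s: float = DEFAULT_EPOCH_S,
    min_beats: int = DEFAULT_MIN_BEATS,
    with_morphology: bool = True,
) -> tuple[BeatSeries, pd.DataFrame]:
    """Detect fiducials, extract reference BP, filter artifacts and aggregate
    one subject's record into a 15-s epoch table with train/test split."""
    r_times = detect_r_peaks(rec.ecg, rec.fs_ecg)
    feet = detect_ppg_feet(rec.ppg, rec.fs_ppg, r_times)
    beats = compute_pat_hr(r_times, feet)
    beats = extract_beat_bp(rec.art, rec.fs_art, beats)
    beats = filter_arterial_artifacts(beats)
    if with_morphology:
        beats.features = beat_morphology(
            rec.ppg, rec.fs_ppg, beats.ppg_foot_time, beats.pat, beats.hr,
        )
    epochs = aggregate_epochs(
        beats, epoch_s=epoch_s, min_beats=min_beats, subject_id=rec.subject_id,
    )
    return beats, epochs
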
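"""Fiducial detectors, beat series, artifact filter, epochs and QC."""

import numpy as np
import pandas as pd
import pytest

from cuffless_bp.exceptions import InsufficientDataError, InvalidRecordError
from cuffless_bp.synthetic_cohort import inject_artifacts
from cuffless_bp.waveform_processing import (
    aggregate_epochs,
    detect_ppg_feet,
    detect_r_peaks,
    process_record,
    qc_subject,
)
from cuffless_bp.waveform_processing.beats import (
    BeatSeries,
    compute_pat_hr,
    extract_beat_bp,
    filter_arterial_artifacts,
)

from conftest import FS


# ------------------------------------------------------------- fiducials


def test_r_peak_count_and_spacing(constant_record):
    r = detect_r_peaks(constant_record.ecg[: int(60 * FS)], FS)
    assert abs(len(r) - 75) <= 1
    assert np.allclose(np.diff(r), 0.8, atol=1.0 / FS)


def test_flat_ecg_gives_empty_result():
    assert len(detect_r_peaks(np.zeros(int(10 * FS)), FS)) == 0


def test_too_short_ecg_rejected():
    with pytest.raises(InsufficientDataError):
        detect_r_peaks(np.zeros(10), FS)


def test_noise_burst_does_not_disturb_peaks_elsewhere(stable_record):
    clean = detect_r_peaks(stable_record.ecg, FS)
    noisy_rec = inject_artifacts(stable_record, 15.0, seed=2, kinds=("noise_burst",))
    assert noisy_rec.artifact_log
    noisy = detect_r_peaks(noisy_rec.ecg, FS)
    in_burst = lambda t: any(s - 0.5 <= t <= e + 0.5 for s, e, _ in noisy_rec.artifact_log)
    clean_out = np.array([t for t in clean if not in_burst(t)])
    noisy_out = np.array([t for t in noisy if not in_burst(t)])
    assert len(clean_out) == len(noisy_out)
    assert np.allclose(clean_out, noisy_out, atol=1e-9)


def test_feet_recover_truth_pat(stable_record):
    rec = stable_record
    r = detect_r_peaks(rec.ecg, FS)
    feet = detect_ppg_feet(rec.ppg, FS, r)
    truth_feet = rec.truth.beat_times + rec.truth.pat_ms / 1000.0
    errs = []
    for f in feet[np.isfinite(feet)]:
        errs.append(np.min(np.abs(truth_feet - f)))
    assert np.isfinite(feet).mean() > 0.98
    assert np.median(errs) <= 1.0 / FS


def test_flat_ppg_window_yields_no_foot(stable_record):
    ppg = stable_record.ppg.copy()
    r = detect_r_peaks(stable_record.ecg, FS)
    k = 20
    i0 = int(r[k] * FS)
    i1 = int(r[k + 1] * FS)
    ppg[i0:i1] = ppg[i0]
    feet = detect_ppg_feet(ppg, FS, r)
    assert np.isnan(feet[k])


def test_detect_feet_requires_r_times(stable_record):
    with pytest.raises(InsufficientDataError):
        detect_ppg_feet(stable_record.ppg, FS, np.array([]))


# ------------------------------------------------------------ beat series


def test_compute_pat_hr_arithmetic():
    beats = compute_pat_hr(np.array([0.0, 0.8, 1.6]),
                           np.array([0.25, 1.05, 1.85]))
    assert np.allclose(beats.pat, [250.0, 250.0, 250.0])
    assert np.allclose(beats.hr[:2], [75.0, 75.0])
    assert beats.valid[:2].all()
    assert not beats.valid[2] and beats.invalid_reason[2] == "no_rr"


def test_foot_before_r_marks_negative_pat():
    beats = compute_pat_hr(np.array([0.0, 0.8, 1.6]),
                           np.array([-0.05, 1.05, 1.85]))
    assert not beats.valid[0]
    assert beats.invalid_reason[0] == "negative_pat"


def test_pat_exceeding_rr_invalid():
    beats = compute_pat_hr(np.array([0.0, 0.8, 1.6]),
                           np.array([0.81, 1.05, 1.85]))
    assert not beats.valid[0]
    assert beats.invalid_reason[0] == "pat_exceeds_rr"


def test_non_increasing_r_times_rejected():
    with pytest.raises(InvalidRecordError):
        compute_pat_hr(np.array([0.0, 0.8, 0.8]), np.array([0.2, 1.0, 1.0]))


def test_extract_beat_bp_constant_signal_then_filtered():
    beats = compute_pat_hr(np.arange(0, 8, 0.8), np.arange(0, 8, 0.8) + 0.25)
    art = np.full(int(8 * FS), 80.0)
    beats = extract_beat_bp(art, FS, beats)
    assert np.allclose(beats.sbp[:-1], 80.0)
    assert np.allclose(beats.dbp[:-1], 80.0)
    filtered = filter_arterial_artifacts(beats)
    assert not filtered.valid[:-1].any()
    assert (filtered.invalid_reason[:-1] == "low_pulse_pressure").all()


def test_flush_and_flatline_beats_invalidated(stable_record):
    rec = inject_artifacts(stable_record, 25.0, seed=13,
                           kinds=("flush_square_wave", "flatline_detachment"))
    assert rec.artifact_log
    beats, _ = process_record(rec, with_morphology=False)
    for s, e, kind in rec.artifact_log:
        inside = (beats.r_time >= s + 1.0) & (beats.r_time <= e - 1.5)
        if inside.sum() == 0:
            continue
        assert (~beats.valid[inside]).any(), f"no beat invalidated inside {kind}"


def test_clean_record_all_beats_valid(stable_record):
    beats, _ = process_record(stable_record, with_morphology=False)
    # every beat except the terminal no-RR beat passes the filter
    assert beats.valid[:-1].all()


# ---------------------------------------------------------------- epochs


def _constant_beats(n=60, hr=60.0, mapv=80.0, pat=250.0):
    r = np.arange(n) * 60.0 / hr
    rr = np.full(n, 60.0 / hr)
    return BeatSeries(
        r_time=r, ppg_foot_time=r + pat / 1000.0, pat=np.full(n, pat),
        rr=rr, hr=np.full(n, hr), sbp=np.full(n, 120.0),
        dbp=np.full(n, 60.0), map=np.full(n, mapv),
    )


def test_epoch_means_of_constant_beats():
    epochs = aggregate_epochs(_constant_beats(), epoch_s=15.0, min_beats=5)
    assert len(epochs) == 4
    assert np.allclose(epochs["ref_map"], 80.0)
    assert np.allclose(epochs["pat"], 250.0)
    assert (epochs["n_valid_beats"] >= 14).all()


def test_epoch_dropped_when_all_beats_invalid():
    beats = _constant_beats()
    beats.mark_invalid((beats.r_time >= 15.0) & (beats.r_time < 30.0), "sbp_jump")
    epochs = aggregate_epochs(beats, epoch_s=15.0, min_beats=5)
    assert len(epochs) == 3
    starts = epochs["epoch_start"].to_numpy()
    assert 15.0 not in starts


def test_split_balance():
    for n in (10, 11):
        epochs = aggregate_epochs(_constant_beats(15 * n), epoch_s=15.0, min_beats=5)
        counts = epochs["split"].value_counts()
        assert abs(counts.get("train", 0) - counts.get("test", 0)) <= 1
        # train strictly precedes test in time
        tmax = epochs.loc[epochs["split"] == "train", "epoch_start"].max()
        tmin = epochs.loc[epochs["split"] == "test", "epoch_start"].min()
        assert tmax < tmin


def test_bad_epoch_width_rejected():
    with pytest.raises(InvalidRecordError):
        aggregate_epochs(_constant_beats(), epoch_s=0.0)


# ------------------------------------------------------------------- QC


def _epochs_for_qc(n, sd_first=5.0, sd_second=5.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    sbp = np.concatenate([130 + sd_first * rng.standard_normal(half),
                          130 + sd_second * rng.standard_normal(n - half)])
    return pd.DataFrame({
        "subject_id": "s0",
        "epoch_start": np.arange(n) * 15.0,
        "ref_sbp": sbp, "ref_dbp": 60.0, "ref_map": 83.0,
        "pat": 250.0, "hr": 75.0, "n_valid_beats": 10,
        "split": ["train"] * half + ["test"] * (n - half),
    })


def _beats_with_ratio(ratio, n=1000):
    beats = _constant_beats(n)
    beats.valid[: int(n * (1 - ratio))] = False
    return beats


def test_qc_all_criteria_pass():
    rep = qc_subject(_epochs_for_qc(300), _beats_with_ratio(0.9))
    assert rep.included and rep.failed_criteria == []


def test_qc_short_recording_excluded():
    rep = qc_subject(_epochs_for_qc(150), _beats_with_ratio(0.9))
    assert not rep.included
    assert rep.failed_criteria == ["short_recording"]


def test_qc_low_train_variation_excluded():
    rep = qc_subject(_epochs_for_qc(300, sd_first=0.5, sd_second=12.0),
                     _beats_with_ratio(0.9))
    assert not rep.included
    assert "low_train_variation" in rep.failed_criteria


def test_qc_low_valid_ratio_excluded():
    rep = qc_subject(_epochs_for_qc(300), _beats_with_ratio(0.4))
    assert not rep.included
    assert "low_valid_ratio" in rep.failed_criteria
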
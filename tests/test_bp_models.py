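"""Population PAT models, PPG features, individualized models, calibration."""

import numpy as np
import pandas as pd
import pytest

from cuffless_bp.bp_models import (
    CalibrationState,
    calibrate,
    ensure_distinct_cohort,
    extract_ppg_features,
    fit_generalized_pat_model,
    fit_individualized_model,
    fit_pat_only_model,
    load_model,
    predict,
    save_model,
)
from cuffless_bp.exceptions import (
    CalibrationWindowError,
    ConfigError,
    InsufficientDataError,
    RankDeficientDesignError,
    SplitLeakageError,
)

BETA = dict(beta0=180.0, beta_pat=-0.6, beta_hr=0.15, beta_inter=-0.0004)


def _linear_cohort(n_subj=4, n_epochs=200, noise_sd=0.0, seed=0,
                   hr_spread=15.0, beta=BETA):
    """Pooled epoch table whose reference BP follows a known linear law."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        pat = rng.uniform(200, 300, n_epochs)
        hr = 75 + hr_spread * rng.standard_normal(n_epochs)
        y = (beta["beta0"] + beta["beta_pat"] * pat + beta["beta_hr"] * hr
             + beta["beta_inter"] * pat * hr)
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, n_epochs)
        rows.append(pd.DataFrame({
            "subject_id": f"s{s}", "epoch_start": np.arange(n_epochs) * 15.0,
            "ref_sbp": y, "ref_dbp": y - 60, "ref_map": y - 40,
            "pat": pat, "hr": hr,
        }))
    return pd.concat(rows, ignore_index=True)


def test_generalized_model_exact_recovery_noiseless():
    cohort = _linear_cohort()
    m = fit_generalized_pat_model(cohort, "sbp", cohort_id="c1")
    assert m.beta0 == pytest.approx(BETA["beta0"], rel=1e-6)
    assert m.beta_pat == pytest.approx(BETA["beta_pat"], rel=1e-6)
    assert m.beta_hr == pytest.approx(BETA["beta_hr"], rel=1e-6)
    assert m.beta_inter == pytest.approx(BETA["beta_inter"], rel=1e-6)


def test_generalized_model_unbiased_under_noise():
    """Monte-Carlo: mean coefficient estimate within 2 SE of truth at
    noise SD 3 mmHg."""
    reps, est = 200, []
    for r in range(reps):
        cohort = _linear_cohort(n_subj=4, n_epochs=500, noise_sd=3.0, seed=r)
        m = fit_generalized_pat_model(cohort, "sbp")
        est.append([m.beta0, m.beta_pat, m.beta_hr, m.beta_inter])
    est = np.array(est)
    truth = np.array([BETA["beta0"], BETA["beta_pat"], BETA["beta_hr"],
                      BETA["beta_inter"]])
    bias = est.mean(axis=0) - truth
    se = est.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(bias) <= 2.0 * se + 1e-12)


def test_constant_hr_design_is_rank_deficient():
    cohort = _linear_cohort(hr_spread=0.0)
    with pytest.raises(RankDeficientDesignError):
        fit_generalized_pat_model(cohort, "sbp")


def test_pat_only_exact_recovery():
    beta = dict(beta0=200.0, beta_pat=-0.5, beta_hr=0.0, beta_inter=0.0)
    cohort = _linear_cohort(beta=beta)
    m = fit_pat_only_model(cohort, "sbp")
    assert m.beta0 == pytest.approx(200.0, rel=1e-6)
    assert m.beta_pat == pytest.approx(-0.5, rel=1e-6)
    assert m.is_pat_only


def test_pat_only_matches_generalized_when_hr_negligible():
    """With a negligible true HR coefficient the two population models make
    near-identical predictions (pooled correlation > 0.99)."""
    beta = dict(beta0=190.0, beta_pat=-0.55, beta_hr=0.0, beta_inter=0.0)
    cohort = _linear_cohort(noise_sd=2.0, beta=beta, seed=5)
    g = fit_generalized_pat_model(cohort, "sbp")
    p = fit_pat_only_model(cohort, "sbp")
    r = np.corrcoef(predict(g, cohort), predict(p, cohort))[0, 1]
    assert r > 0.99


def test_small_cohort_rejected():
    cohort = _linear_cohort(n_subj=1)
    with pytest.raises(InsufficientDataError):
        fit_generalized_pat_model(cohort, "sbp")


def test_cohort_identity_guard():
    m = fit_generalized_pat_model(_linear_cohort(), "sbp", cohort_id="exercise")
    ensure_distinct_cohort(m, "icu")
    with pytest.raises(ConfigError):
        ensure_distinct_cohort(m, "exercise")


def test_predict_arithmetic_and_offset():
    from cuffless_bp.bp_models import LinearPATModel
    m = LinearPATModel(beta0=100.0, beta_pat=-0.2, beta_hr=0.1,
                       beta_inter=0.0, target="sbp")
    epochs = pd.DataFrame({"epoch_start": [0.0], "pat": [250.0], "hr": [60.0]})
    assert predict(m, epochs)[0] == pytest.approx(56.0)
    cal = CalibrationState().add(0.0, 5.0)
    assert predict(m, epochs, cal)[0] == pytest.approx(61.0)


def test_model_json_roundtrip(tmp_path):
    m = fit_generalized_pat_model(_linear_cohort(), "map", cohort_id="c9")
    save_model(m, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert back.to_dict() == m.to_dict()


# ------------------------------------------------------------ PPG features


def _pulse(fs=250.0, rr=0.8, rise_ms=150.0, amp=1.0, width_scale=1.0):
    """Triangular-ish asymmetric test pulse with known amplitude and rise."""
    n = int(rr * fs)
    t = np.arange(n) / fs * 1000.0
    x = np.zeros(n)
    up = t <= rise_ms
    x[up] = amp * t[up] / rise_ms
    down = ~up
    tau = 220.0 * width_scale
    x[down] = amp * np.exp(-(t[down] - rise_ms) / tau)
    return x


def test_feature_amplitude_and_rise_time():
    fs = 250.0
    f = extract_ppg_features(_pulse(fs), fs)
    assert f["amplitude"] == pytest.approx(1.0, rel=0.02)
    assert f["rise_time"] == pytest.approx(150.0, abs=1000.0 / fs)


def test_feature_scaling_linearity():
    fs = 250.0
    f1 = extract_ppg_features(_pulse(fs), fs)
    f2 = extract_ppg_features(_pulse(fs, amp=2.0), fs)
    assert f2["amplitude"] == pytest.approx(2.0 * f1["amplitude"], rel=1e-6)
    assert f2["rise_time"] == f1["rise_time"]
    assert f2["width_50"] == f1["width_50"]


def test_feature_width_monotone_in_template_width():
    fs = 250.0
    widths = [extract_ppg_features(_pulse(fs, width_scale=w), fs)["width_50"]
              for w in (0.6, 0.9, 1.2, 1.5)]
    assert all(a < b for a, b in zip(widths, widths[1:]))


def test_flat_window_has_no_features():
    assert extract_ppg_features(np.zeros(200), 250.0) is None


# ------------------------------------------------------- individualized


def _subject_epochs(n=60, seed=0, split="train"):
    rng = np.random.default_rng(seed)
    feats = {name: rng.uniform(0.5, 1.5, n) for name in
             ("pat", "hr", "amplitude", "rise_time", "width_50",
              "pulse_area", "reflection_ratio")}
    y = (120 - 20 * feats["amplitude"] + 5 * feats["pat"] + 3 * feats["hr"])
    df = pd.DataFrame(feats)
    df["ref_sbp"] = y
    df["ref_dbp"] = y - 55
    df["ref_map"] = y - 37
    df["subject_id"] = "s0"
    df["epoch_start"] = np.arange(n) * 15.0
    df["split"] = split
    return df


def test_individualized_interpolates_exact_linear_subject():
    train = _subject_epochs()
    m = fit_individualized_model(train, "sbp", alpha=1e-8)
    pred = predict(m, train)
    assert np.abs(pred - train["ref_sbp"]).mean() < 1e-4


def test_individualized_refuses_test_split():
    with pytest.raises(SplitLeakageError):
        fit_individualized_model(_subject_epochs(split="test"), "sbp")


def test_individualized_needs_enough_epochs():
    with pytest.raises(InsufficientDataError):
        fit_individualized_model(_subject_epochs(n=10), "sbp")


def test_individualized_cv_alpha_selection_runs():
    m = fit_individualized_model(_subject_epochs(n=80), "sbp", alpha="cv")
    assert m.alpha > 0


# ------------------------------------------------------------ calibration


def test_calibration_zeroes_window_mean_error():
    t = np.arange(24) * 15.0
    ref = np.full(24, 120.0)
    pred = ref + 7.0
    state = calibrate(pred, ref, t, at=0.0)
    assert state.offsets[0][1] == pytest.approx(-7.0)
    corrected = state.apply(pred, t)
    win = t < 180.0
    assert abs((corrected - ref)[win].mean()) < 1e-9


def test_recalibration_sequence_uses_only_past_offsets():
    t = np.arange(48) * 15.0
    ref = np.where(t < 360.0, 120.0, 123.7)   # relevel-style step at 360 s
    pred = np.full(48, 115.0)
    state = calibrate(pred, ref, t, at=0.0)
    state = calibrate(pred, ref, t, at=360.0, state=state)
    assert len(state.offsets) == 2
    off = state.offset_at(t)
    assert np.allclose(off[t < 360.0], 5.0)
    assert np.allclose(off[t >= 360.0], 8.7)


def test_calibration_idempotent():
    t = np.arange(24) * 15.0
    ref = 120 + np.sin(t / 50.0)
    pred = ref - 3.0
    s1 = calibrate(pred, ref, t, at=0.0)
    s2 = calibrate(pred, ref, t, at=0.0, state=s1)
    assert s2.offsets == s1.offsets


def test_calibration_translation_equivariance():
    rng = np.random.default_rng(8)
    t = np.arange(40) * 15.0
    ref = 120 + rng.standard_normal(40)
    pred = ref + rng.standard_normal(40)
    base = calibrate(pred, ref, t, at=0.0).apply(pred, t)
    shifted = calibrate(pred, ref + 11.0, t, at=0.0).apply(pred, t)
    assert np.allclose(shifted - base, 11.0)


def test_calibration_window_must_be_covered():
    t = np.arange(8) * 15.0   # only 120 s of epochs
    with pytest.raises(CalibrationWindowError):
        calibrate(np.ones(8), np.ones(8), t, at=0.0)
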
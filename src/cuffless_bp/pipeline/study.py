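"""End-to-end study replica.

Stages, in order: generate the general-population exercise cohort and fit
the population PAT models on its pooled epochs; generate and process the
ICU evaluation cohort; apply subject-level QC; fit per-subject
individualized models on each subject's train split; statically calibrate
every model at the start of each subject's test period (and again at logged
transducer-relevel events); predict over the test split; and compare the
models with the full agreement-statistics suite.  A hypotension+tachycardia
episode-tracking table (does each model predict the *direction* of the MAP
change?) is assembled along the way.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from ..agreement_stats import (
    AgreementSummary,
    ModelComparison,
    compare_models,
    make_pairs,
    summarize_pairs,
)
from ..bp_models import (
    CalibrationState,
    calibrate,
    ensure_distinct_cohort,
    fit_generalized_pat_model,
    fit_individualized_model,
    fit_pat_only_model,
    predict,
)
from ..exceptions import (
    CalibrationWindowError,
    EmptyCohortError,
    InsufficientDataError,
    SplitLeakageError,
)
from ..synthetic_cohort import LABEL_HYPO_TACHY, generate_subject
from ..waveform_processing import process_record, qc_subject
from .config import StudyConfig

log = logging.getLogger(__name__)

MODEL_LABELS = ("generalized", "pat_only", "individualized")
_EXERCISE_COHORT_ID = "exercise"
_ICU_COHORT_ID = "icu"


def derive_seed(seed: int, tag: int) -> int:
    """Independent integer sub-stream seed (< 2^31) from (seed, tag)."""
    return int(np.random.SeedSequence([int(seed), int(tag)]).generate_state(1)[0] % (2**31))


@dataclass
class StudyReport:
    """Everything the study produces, ready for serialization."""

    summaries: dict                   # target -> label -> AgreementSummary
    comparisons: dict                 # target -> ModelComparison
    patonly_vs_generalized: dict      # target -> {"pearson": r, "r2": r^2}
    qc_ledger: list                   # per generated subject, in order
    episode_tracking: pd.DataFrame    # hypotension+tachycardia direction table
    stage_counters: dict
    provenance: dict
    pairs: dict = field(default_factory=dict)   # (label, target) -> DataFrame


# ----------------------------------------------------------------- stages


def build_exercise_epochs(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Process the isometric-exercise cohort into one pooled epoch table."""
    cfg = config.exercise_cohort
    ex_seed = derive_seed(seed, 101)
    tables = []
    for idx in range(cfg.n_subjects):
        rec = generate_subject(cfg, ex_seed, idx)
        _beats, epochs = process_record(
            rec, epoch_s=config.epoch_s, min_beats=config.min_beats_per_epoch,
            with_morphology=False,
        )
        tables.append(epochs)
    pooled = pd.concat(tables, ignore_index=True)
    log.info("exercise cohort: %d subjects, %d pooled epochs", cfg.n_subjects, len(pooled))
    return pooled


def fit_population_models(exercise_epochs: pd.DataFrame, targets) -> tuple[dict, dict]:
    general = {t: fit_generalized_pat_model(exercise_epochs, t, cohort_id=_EXERCISE_COHORT_ID)
               for t in targets}
    pat_only = {t: fit_pat_only_model(exercise_epochs, t, cohort_id=_EXERCISE_COHORT_ID)
                for t in targets}
    return general, pat_only


def build_icu_subject(config: StudyConfig, seed: int, idx: int) -> dict:
    """Generate + process + QC one ICU subject; returns all evaluation inputs."""
    icu_seed = derive_seed(seed, 202)
    rec = generate_subject(config.cohort, icu_seed, idx)
    beats, epochs = process_record(
        rec, epoch_s=config.epoch_s, min_beats=config.min_beats_per_epoch,
    )
    if len(epochs):
        qc = qc_subject(
            epochs, beats,
            min_valid_ratio=config.qc_min_valid_ratio,
            min_pairs=config.qc_min_pairs,
            min_sd_ratio=config.qc_min_sd_ratio,
        )
    else:
        from ..waveform_processing.qc import QCReport
        qc = QCReport(subject_id=rec.subject_id, valid_ratio=0.0, n_pairs=0,
                      sd_first_half=0.0, sd_total=0.0, included=False,
                      failed_criteria=["short_recording"])
    episodes = []
    traj = rec.truth.trajectory if rec.truth is not None else None
    if traj is not None:
        episodes = _label_intervals(traj.time, traj.event_labels, LABEL_HYPO_TACHY)
    reason_counts = Counter(r for r in beats.invalid_reason if r)
    return {
        "subject_id": rec.subject_id,
        "epochs": epochs,
        "qc": qc,
        "relevels": list(rec.relevel_log),
        "episodes": episodes,
        "counters": {
            "beats": len(beats),
            "beats_valid": int(beats.valid.sum()),
            "epochs": len(epochs),
            **{f"invalid_{k}": v for k, v in reason_counts.items()},
        },
    }


def _label_intervals(time: np.ndarray, labels: np.ndarray, label: str):
    mask = np.asarray(labels == label)
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if mask[e + 1]]
    ends = [int(e) for e in edges if mask[e]]
    if mask[-1]:
        ends.append(len(mask) - 1)
    return [(float(time[s]), float(time[e])) for s, e in zip(starts, ends)]


def _calibrated_predictions(model, test: pd.DataFrame, target: str,
                            relevels, config: StudyConfig) -> np.ndarray:
    """Static calibration at the test-period start and at each relevel."""
    ycol = f"ref_{target}"
    raw = predict(model, test)
    ref = test[ycol].to_numpy(float)
    tstart = float(test["epoch_start"].iloc[0])
    state = calibrate(raw, ref, test["epoch_start"], tstart,
                      window_s=config.cal_window_s)
    for rt, _cm in sorted(relevels):
        after = test["epoch_start"][test["epoch_start"] >= rt]
        if len(after) == 0 or rt <= tstart:
            continue
        try:
            calibrate(raw, ref, test["epoch_start"], float(after.iloc[0]),
                      window_s=config.cal_window_s, state=state)
        except CalibrationWindowError:
            log.info("skipping recalibration at %.0f s (window not covered)", rt)
    return state.apply(raw, test["epoch_start"].to_numpy(float))


def evaluate_cohort(subjects: list[dict], general: dict, pat_only: dict,
                    config: StudyConfig, provenance: dict | None = None) -> StudyReport:
    """QC-gate subjects, fit individualized models, calibrate, predict on the
    test split and assemble the full report."""
    for t in config.targets:
        ensure_distinct_cohort(general[t], _ICU_COHORT_ID)
        ensure_distinct_cohort(pat_only[t], _ICU_COHORT_ID)

    pair_rows: dict = {(lbl, t): [] for lbl in MODEL_LABELS for t in config.targets}
    episode_rows = []
    qc_ledger = []
    counters: Counter = Counter()

    for sub in subjects:
        qc = sub["qc"]
        counters.update(sub.get("counters", {}))
        if not qc.included:
            qc_ledger.append(qc.to_dict())
            continue
        epochs = sub["epochs"]
        train = epochs[epochs["split"] == "train"].reset_index(drop=True)
        test = epochs[epochs["split"] == "test"].reset_index(drop=True)
        try:
            preds = {}
            for t in config.targets:
                ind = fit_individualized_model(train, t, alpha=config.ridge_alpha)
                for lbl, model in (("generalized", general[t]),
                                   ("pat_only", pat_only[t]),
                                   ("individualized", ind)):
                    preds[(lbl, t)] = _calibrated_predictions(
                        model, test, t, sub["relevels"], config)
        except (InsufficientDataError, SplitLeakageError, CalibrationWindowError) as exc:
            qc.included = False
            qc.failed_criteria = list(qc.failed_criteria) + ["model_fitting_failed"]
            log.warning("subject %s dropped at modelling stage: %s", qc.subject_id, exc)
            qc_ledger.append(qc.to_dict())
            continue
        qc_ledger.append(qc.to_dict())
        counters["subjects_included"] += 1
        for (lbl, t), est in preds.items():
            pair_rows[(lbl, t)].append(make_pairs(
                test["subject_id"], test["epoch_start"], test[f"ref_{t}"], est))
        episode_rows += _episode_tracking_rows(sub, test, preds, config)

    if counters["subjects_included"] == 0:
        raise EmptyCohortError("no subject survived QC and model fitting", qc_ledger)

    pairs = {k: pd.concat(v, ignore_index=True) for k, v in pair_rows.items() if v}
    summaries = {
        t: {lbl: summarize_pairs(pairs[(lbl, t)]) for lbl in MODEL_LABELS}
        for t in config.targets
    }
    comparisons = {
        t: compare_models(
            pairs[("generalized", t)], pairs[("individualized", t)],
            label_a="generalized", label_b="individualized",
            loss=config.dm_loss, alpha=config.significance_alpha,
        )
        for t in config.targets
    }
    patonly_vs_general = {}
    for t in config.targets:
        x = pairs[("generalized", t)]["estimate"].to_numpy()
        y = pairs[("pat_only", t)]["estimate"].to_numpy()
        r = float(np.corrcoef(x, y)[0, 1])
        patonly_vs_general[t] = {"pearson": r, "r2": r * r}

    episode_df = pd.DataFrame(
        episode_rows,
        columns=["subject_id", "episode_start", "episode_end", "delta_ref_map",
                 "delta_generalized", "delta_pat_only", "delta_individualized"],
    )
    return StudyReport(
        summaries=summaries, comparisons=comparisons,
        patonly_vs_generalized=patonly_vs_general,
        qc_ledger=qc_ledger, episode_tracking=episode_df,
        stage_counters=dict(counters),
        provenance=provenance or {}, pairs=pairs,
    )


def _episode_tracking_rows(sub, test: pd.DataFrame, preds: dict, config: StudyConfig):
    """Per hypotension+tachycardia episode in the test period: reference MAP
    change vs each model's predicted change (pre-episode mean to trough)."""
    if "map" not in config.targets or len(test) == 0:
        return []
    rows = []
    t_ep = test["epoch_start"].to_numpy(float)
    ref = test["ref_map"].to_numpy(float)
    for (s, e) in sub["episodes"]:
        if s < t_ep[0]:
            continue   # episode not (fully) in the test period
        pre = (t_ep >= s - 240.0) & (t_ep < s)
        inside = (t_ep >= s) & (t_ep <= e)
        if pre.sum() < 2 or inside.sum() < 3:
            continue
        trough_pos = np.flatnonzero(inside)[np.argmin(ref[inside])]
        sel = np.zeros(len(t_ep), bool)
        sel[max(trough_pos - 1, 0): trough_pos + 2] = True
        sel &= inside
        d_ref = float(ref[sel].mean() - ref[pre].mean())
        deltas = {}
        for lbl in MODEL_LABELS:
            est = preds[(lbl, "map")]
            deltas[lbl] = float(est[sel].mean() - est[pre].mean())
        rows.append((sub["subject_id"], s, e, d_ref, deltas["generalized"],
                     deltas["pat_only"], deltas["individualized"]))
    return rows


# -------------------------------------------------------------- top level


def run_study(config: StudyConfig, seed: int, out_dir=None) -> StudyReport:
    """Run the complete study replica for one seed.

    Raises :class:`EmptyCohortError` (with the QC ledger attached) if no
    subject survives quality control.  When ``out_dir`` is given, all
    intermediate tables and the rendered report are written there.
    """
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    provenance = {
        "seed": int(seed),
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "package_version": __version__,
    }
    exercise_epochs = build_exercise_epochs(config, seed)
    general, pat_only = fit_population_models(exercise_epochs, config.targets)
    subjects = [build_icu_subject(config, seed, idx)
                for idx in range(config.cohort.n_subjects)]
    report = evaluate_cohort(subjects, general, pat_only, config, provenance)
    if out_dir is not None:
        from .report import write_study_outputs
        write_study_outputs(report, out_dir, exercise_epochs=exercise_epochs,
                            icu_epochs=pd.concat([s["epochs"] for s in subjects],
                                                 ignore_index=True),
                            general=general, pat_only=pat_only)
    return report
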
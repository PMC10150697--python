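"""Deterministic report rendering (JSON / CSV / markdown)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ..exceptions import ConfigError
from .study import MODEL_LABELS, StudyReport

# human-readable row labels for the markdown table
_MD_ROWS = [
    ("mean_error", "Mean error, mmHg"),
    ("mae", "Mean absolute error, mmHg"),
    ("sd_mae", "SD of absolute errors, mmHg"),
    ("sd_of_errors", "SD of errors, mmHg"),
    ("median_abs_error", "Median of absolute errors, mmHg"),
    ("pct_within_5", "Absolute errors within 5 mmHg, %"),
    ("pct_within_10", "Absolute errors within 10 mmHg, %"),
    ("pct_within_15", "Absolute errors within 15 mmHg, %"),
    ("ba_bias", "Bland-Altman bias, mmHg"),
    ("ba_loa_low", "Lower 95% limit of agreement, mmHg"),
    ("ba_loa_high", "Upper 95% limit of agreement, mmHg"),
    ("rmcorr", "Repeated measures correlation coefficient"),
    ("pearson_pooled", "Correlation coefficient, all subjects pooled"),
    ("agg_r2", "Linear regression of aggregated data, R2"),
    ("aic", "Akaike's information criterion"),
    ("bic", "Bayesian information criterion"),
]

_COMPONENT_TITLES = {
    "sbp": "Systolic blood pressure",
    "dbp": "Diastolic blood pressure",
    "map": "Mean arterial pressure",
}


def _jsonify(obj):
    """JSON-safe normalization: tuples -> lists, numpy scalars -> python,
    NaN/inf -> None (so serialized reports compare and round-trip exactly)."""
    import numpy as np
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_dict(report: StudyReport) -> dict:
    return _jsonify({
        "summaries": {
            t: {lbl: s.to_dict() for lbl, s in per_model.items()}
            for t, per_model in report.summaries.items()
        },
        "comparisons": {t: c.to_dict() for t, c in report.comparisons.items()},
        "patonly_vs_generalized": report.patonly_vs_generalized,
        "qc_ledger": report.qc_ledger,
        "episode_tracking": report.episode_tracking.to_dict(orient="records"),
        "stage_counters": report.stage_counters,
        "provenance": report.provenance,
    })


def summary_table(report: StudyReport) -> pd.DataFrame:
    """Long-format table: one row per (component, model, metric)."""
    rows = []
    for t, per_model in report.summaries.items():
        for lbl, s in per_model.items():
            for metric, value in s.to_dict().items():
                rows.append((t, lbl, metric, value))
    return pd.DataFrame(rows, columns=["component", "model", "metric", "value"])


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.3f}"
    return str(v)


def markdown_report(report: StudyReport) -> str:
    lines = ["# Cuffless BP study report", ""]
    for t, per_model in report.summaries.items():
        lines.append(f"## {_COMPONENT_TITLES.get(t, t)}")
        lines.append("")
        header = "| Metric | " + " | ".join(MODEL_LABELS) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(MODEL_LABELS) + 1))
        for key, label in _MD_ROWS:
            vals = [_fmt(getattr(per_model[lbl], key)) for lbl in MODEL_LABELS]
            lines.append(f"| {label} | " + " | ".join(vals) + " |")
        comp = report.comparisons[t]
        lines.append(
            f"| Diebold-Mariano comparison | {comp.verdict} "
            f"(p = {_fmt(comp.p_dm_pooled)}) | | |")
        lines.append("")
    inc = sum(1 for q in report.qc_ledger if q["included"])
    lines.append(f"Included subjects: {inc} / {len(report.qc_ledger)}")
    lines.append("")
    return "\n".join(lines)


def render_report(report: StudyReport, fmt: str, out_dir) -> list[Path]:
    """Write the report in one format; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))
        return [path]
    if fmt == "csv":
        p1 = out_dir / "report_summary.csv"
        summary_table(report).to_csv(p1, index=False)
        p2 = out_dir / "report_comparisons.csv"
        pd.DataFrame([{"component": t, **c.to_dict()} for t, c in
                      report.comparisons.items()]).to_csv(p2, index=False)
        return [p1, p2]
    if fmt == "markdown":
        path = out_dir / "report.md"
        path.write_text(markdown_report(report))
        return [path]
    raise ConfigError(f"unknown report format {fmt!r} (json|csv|markdown)")


def write_study_outputs(report: StudyReport, out_dir, *, exercise_epochs=None,
                        icu_epochs=None, general=None, pat_only=None) -> None:
    """Write every intermediate table plus all three report renderings."""
    from ..bp_models import save_model
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if exercise_epochs is not None:
        exercise_epochs.to_csv(out_dir / "exercise_epochs.csv", index=False)
    if icu_epochs is not None:
        icu_epochs.to_csv(out_dir / "icu_epochs.csv", index=False)
    for (lbl, t), df in report.pairs.items():
        df.to_csv(out_dir / f"pairs_{lbl}_{t}.csv", index=False)
    with open(out_dir / "qc_ledger.jsonl", "w") as fh:
        for row in report.qc_ledger:
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    report.episode_tracking.to_csv(out_dir / "episode_tracking.csv", index=False)
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for t, model in (general or {}).items():
        save_model(model, models_dir / f"generalized_{t}.json")
    for t, model in (pat_only or {}).items():
        save_model(model, models_dir / f"pat_only_{t}.json")
    for fmt in ("json", "csv", "markdown"):
        render_report(report, fmt, out_dir)
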
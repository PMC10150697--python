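"""BP predictors: population PAT models, subject-specific ridge models,
static calibration and the hydrostatic-bias helper."""

from __future__ import annotations

import json
from pathlib import Path

from .calibration import (
    CalibrationState,
    DEFAULT_CAL_WINDOW_S,
    calibrate,
    hydrostatic_bias,
)
from .features import FEATURE_NAMES, MORPH_FEATURES, beat_morphology, extract_ppg_features
from .individualized import (
    IndividualizedModel,
    fit_individualized_model,
    predict_individualized,
)
from .linear import (
    LinearPATModel,
    TARGETS,
    ensure_distinct_cohort,
    fit_generalized_pat_model,
    fit_pat_only_model,
    predict_linear,
    reference_column,
)

__all__ = [
    "CalibrationState", "DEFAULT_CAL_WINDOW_S", "calibrate", "hydrostatic_bias",
    "FEATURE_NAMES", "MORPH_FEATURES", "beat_morphology", "extract_ppg_features",
    "IndividualizedModel", "fit_individualized_model", "predict_individualized",
    "LinearPATModel", "TARGETS", "ensure_distinct_cohort",
    "fit_generalized_pat_model", "fit_pat_only_model", "predict_linear",
    "reference_column", "predict", "save_model", "load_model",
]


def predict(model, epochs, calibration: CalibrationState | None = None):
    """Dispatch prediction for either model family."""
    if isinstance(model, LinearPATModel):
        return predict_linear(model, epochs, calibration)
    if isinstance(model, IndividualizedModel):
        return predict_individualized(model, epochs, calibration)
    raise TypeError(f"unknown model type {type(model).__name__}")


def save_model(model, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path):
    d = json.loads(Path(path).read_text())
    if d.get("kind") == "individualized_ridge":
        return IndividualizedModel.from_dict(d)
    return LinearPATModel.from_dict(d)
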
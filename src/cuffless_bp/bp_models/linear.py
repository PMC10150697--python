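"""Population-level linear PAT models.

Two variants, both plain ordinary-least-squares fits on pooled epoch data
from a *training* cohort (kept distinct from the evaluation cohort):

* generalized model: BP ~ 1 + PAT + HR + PAT*HR
* PAT-only model:    BP ~ 1 + PAT

Coefficients carry units mmHg, mmHg/ms, mmHg/bpm and mmHg/(ms*bpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import ConfigError, InsufficientDataError, RankDeficientDesignError
from .calibration import CalibrationState

TARGETS = ("sbp", "dbp", "map")


def reference_column(target: str) -> str:
    if target not in TARGETS:
        raise ConfigError(f"target must be one of {TARGETS}, got {target!r}")
    return f"ref_{target}"


@dataclass
class LinearPATModel:
    """Fitted linear PAT(-HR) predictor for one BP component."""

    beta0: float
    beta_pat: float
    beta_hr: float
    beta_inter: float
    target: str
    fit_cohort_id: str = "unknown"
    n_epochs: int = 0
    n_subjects: int = 0

    @property
    def is_pat_only(self) -> bool:
        return self.beta_hr == 0.0 and self.beta_inter == 0.0

    def to_dict(self) -> dict:
        return {
            "kind": "linear_pat",
            "beta0": self.beta0, "beta_pat": self.beta_pat,
            "beta_hr": self.beta_hr, "beta_inter": self.beta_inter,
            "target": self.target, "fit_cohort_id": self.fit_cohort_id,
            "n_epochs": self.n_epochs, "n_subjects": self.n_subjects,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearPATModel":
        d = {k: v for k, v in d.items() if k != "kind"}
        return cls(**d)


def _check_cohort(epochs: pd.DataFrame, min_epochs: int, min_subjects: int) -> None:
    if len(epochs) < min_epochs:
        raise InsufficientDataError(
            f"need >= {min_epochs} pooled epochs, got {len(epochs)}")
    if epochs["subject_id"].nunique() < min_subjects:
        raise InsufficientDataError(
            f"need >= {min_subjects} subjects, got {epochs['subject_id'].nunique()}")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # scale columns before the rank check so ms- and bpm-sized regressors
    # are judged on correlation, not magnitude
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    rank = np.linalg.matrix_rank(X / scale, tol=1e-8)
    if rank < X.shape[1]:
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {X.shape[1]}: coefficients are "
            "unidentifiable (constant or collinear regressors)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_generalized_pat_model(
    cohort_epochs: pd.DataFrame,
    target: str,
    *,
    cohort_id: str = "training_cohort",
) -> LinearPATModel:
    """OLS of one BP component on (PAT, HR, PAT*HR) over a pooled cohort."""
    ycol = reference_column(target)
    _check_cohort(cohort_epochs, min_epochs=50, min_subjects=2)
    pat = cohort_epochs["pat"].to_numpy(float)
    hr = cohort_epochs["hr"].to_numpy(float)
    y = cohort_epochs[ycol].to_numpy(float)
    X = np.column_stack([np.ones_like(pat), pat, hr, pat * hr])
    b = _ols(X, y)
    return LinearPATModel(
        beta0=float(b[0]), beta_pat=float(b[1]), beta_hr=float(b[2]),
        beta_inter=float(b[3]), target=target, fit_cohort_id=cohort_id,
        n_epochs=len(cohort_epochs),
        n_subjects=int(cohort_epochs["subject_id"].nunique()),
    )


def fit_pat_only_model(
    cohort_epochs: pd.DataFrame,
    target: str,
    *,
    cohort_id: str = "training_cohort",
) -> LinearPATModel:
    """OLS of one BP component on PAT alone."""
    ycol = reference_column(target)
    _check_cohort(cohort_epochs, min_epochs=50, min_subjects=2)
    pat = cohort_epochs["pat"].to_numpy(float)
    y = cohort_epochs[ycol].to_numpy(float)
    X = np.column_stack([np.ones_like(pat), pat])
    b = _ols(X, y)
    return LinearPATModel(
        beta0=float(b[0]), beta_pat=float(b[1]), beta_hr=0.0, beta_inter=0.0,
        target=target, fit_cohort_id=cohort_id, n_epochs=len(cohort_epochs),
        n_subjects=int(cohort_epochs["subject_id"].nunique()),
    )


def ensure_distinct_cohort(model: LinearPATModel, eval_cohort_id: str) -> None:
    """Population models must never be evaluated on their fitting cohort."""
    if model.fit_cohort_id == eval_cohort_id:
        raise ConfigError(
            f"model was fitted on cohort {model.fit_cohort_id!r}; evaluation "
            "on the same cohort is not allowed")


def predict_linear(
    model: LinearPATModel,
    epochs: pd.DataFrame,
    calibration: CalibrationState | None = None,
) -> np.ndarray:
    """Apply a linear PAT model to an epoch table (plus any active offset)."""
    for col in ("pat", "hr"):
        if col not in epochs.columns:
            raise InsufficientDataError(f"epoch table lacks required column {col!r}")
    pat = epochs["pat"].to_numpy(float)
    hr = epochs["hr"].to_numpy(float)
    est = (model.beta0 + model.beta_pat * pat + model.beta_hr * hr
           + model.beta_inter * pat * hr)
    if calibration is not None:
        est = calibration.apply(est, epochs["epoch_start"].to_numpy(float))
    return est
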
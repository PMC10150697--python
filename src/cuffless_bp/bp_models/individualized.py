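"""Subject-specific ("individualized") BP models.

A deterministic, small-footprint learner standing in for proprietary
per-patient machine-learning models: ridge regression on standardized
per-epoch features (PAT, HR and PPG morphology), trained strictly on the
subject's train split.  The regularization strength can optionally be chosen
by leave-contiguous-chunk-out cross-validation inside the train split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from ..exceptions import InsufficientDataError, SplitLeakageError
from .calibration import CalibrationState
from .features import FEATURE_NAMES
from .linear import reference_column

DEFAULT_ALPHA = 1.0
_CV_ALPHAS = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
_MIN_TRAIN_EPOCHS = 20


@dataclass
class IndividualizedModel:
    """Ridge model on standardized features for one subject and BP component."""

    subject_id: str
    target: str
    feature_names: tuple
    coef: np.ndarray
    intercept: float
    alpha: float
    mu: np.ndarray        # per-feature standardization mean
    sigma: np.ndarray     # per-feature standardization SD
    train_span: tuple = (np.nan, np.nan)

    def to_dict(self) -> dict:
        return {
            "kind": "individualized_ridge",
            "subject_id": self.subject_id, "target": self.target,
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(), "intercept": self.intercept,
            "alpha": self.alpha, "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(), "train_span": list(self.train_span),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndividualizedModel":
        return cls(
            subject_id=d["subject_id"], target=d["target"],
            feature_names=tuple(d["feature_names"]),
            coef=np.asarray(d["coef"], float), intercept=float(d["intercept"]),
            alpha=float(d["alpha"]), mu=np.asarray(d["mu"], float),
            sigma=np.asarray(d["sigma"], float),
            train_span=tuple(d["train_span"]),
        )


def _design(epochs: pd.DataFrame, names) -> np.ndarray:
    missing = [c for c in names if c not in epochs.columns]
    if missing:
        raise InsufficientDataError(f"epoch table lacks feature columns {missing}")
    return epochs[list(names)].to_numpy(float)


def _fit_ridge(X, y, alpha, mu, sigma):
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit((X - mu) / sigma, y)
    return model


def fit_individualized_model(
    train_epochs: pd.DataFrame,
    target: str,
    *,
    alpha: float | str = DEFAULT_ALPHA,
    feature_names=FEATURE_NAMES,
    min_epochs: int = _MIN_TRAIN_EPOCHS,
) -> IndividualizedModel:
    """Fit one subject's ridge model on its train-split epochs.

    ``alpha`` may be a number or ``"cv"`` (leave-contiguous-chunk-out
    selection over a small grid).  Refuses any epoch labelled ``test``.
    """
    ycol = reference_column(target)
    if "split" in train_epochs.columns and (train_epochs["split"] != "train").any():
        raise SplitLeakageError(
            "train_epochs contains test-split rows; subject-specific models "
            "may only see the first half of a subject's data")
    if len(train_epochs) < min_epochs:
        raise InsufficientDataError(
            f"need >= {min_epochs} train epochs, got {len(train_epochs)}")
    sids = train_epochs["subject_id"].unique() if "subject_id" in train_epochs.columns else ["?"]
    if len(sids) != 1:
        raise InsufficientDataError("individualized models are fit per subject")

    X = _design(train_epochs, feature_names)
    y = train_epochs[ycol].to_numpy(float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    sigma[sigma < 1e-12] = 1.0   # constant features contribute nothing

    if alpha == "cv":
        alpha = _select_alpha(X, y, mu, sigma)
    model = _fit_ridge(X, y, float(alpha), mu, sigma)
    ts = train_epochs["epoch_start"].to_numpy(float) if "epoch_start" in train_epochs.columns else np.array([np.nan])
    return IndividualizedModel(
        subject_id=str(sids[0]), target=target, feature_names=tuple(feature_names),
        coef=np.asarray(model.coef_, float), intercept=float(model.intercept_),
        alpha=float(alpha), mu=mu, sigma=sigma,
        train_span=(float(np.min(ts)), float(np.max(ts))),
    )


def _select_alpha(X, y, mu, sigma, n_chunks: int = 5) -> float:
    """Leave-contiguous-chunk-out CV (chunks respect time order)."""
    n = len(y)
    bounds = np.linspace(0, n, n_chunks + 1).astype(int)
    best_alpha, best_err = _CV_ALPHAS[0], np.inf
    for a in _CV_ALPHAS:
        errs = []
        for k in range(n_chunks):
            lo, hi = bounds[k], bounds[k + 1]
            mask = np.ones(n, bool)
            mask[lo:hi] = False
            if mask.sum() < 5 or (~mask).sum() == 0:
                continue
            m = _fit_ridge(X[mask], y[mask], a, mu, sigma)
            pred = m.predict((X[~mask] - mu) / sigma)
            errs.append(np.mean(np.abs(pred - y[~mask])))
        err = float(np.mean(errs)) if errs else np.inf
        if err < best_err:
            best_alpha, best_err = a, err
    return float(best_alpha)


def predict_individualized(
    model: IndividualizedModel,
    epochs: pd.DataFrame,
    calibration: CalibrationState | None = None,
) -> np.ndarray:
    X = _design(epochs, model.feature_names)
    est = (X - model.mu) / model.sigma @ model.coef + model.intercept
    if calibration is not None:
        est = calibration.apply(est, epochs["epoch_start"].to_numpy(float))
    return est
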
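"""Aggregated-means regression with Gaussian-likelihood AIC/BIC.

Per-subject mean estimated BP is regressed against per-subject mean
reference BP with a simple linear model.  Non-nested models cannot be
compared by a direct test, so the fits are compared numerically on R²,
RMSE, AIC and BIC.  The information criteria use the full Gaussian
log-likelihood with k = 3 estimated parameters (slope, intercept, residual
variance); their absolute values carry the likelihood constant, so only
differences between models fitted to the same subjects are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import InsufficientDataError
from .pairs import check_pairs

_K_PARAMS = 3


@dataclass
class AggregatedRegression:
    slope: float
    intercept: float
    r2: float
    rmse: float
    aic: float
    bic: float
    loglik: float
    n_subjects: int


def aggregated_regression(pairs: pd.DataFrame) -> AggregatedRegression:
    """Regress per-subject mean reference on per-subject mean estimate."""
    check_pairs(pairs, min_rows=4)
    agg = pairs.groupby("subject_id")[["reference", "estimate"]].mean()
    n = len(agg)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 subjects, got {n}")
    x = agg["estimate"].to_numpy(float)
    y = agg["reference"].to_numpy(float)
    if x.std() == 0:
        raise InsufficientDataError("aggregated estimates are constant")
    X = np.column_stack([np.ones_like(x), x])
    (b0, b1), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (b0 + b1 * x)
    rss = float((resid ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = max(rss / n, 1e-300)    # MLE variance
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return AggregatedRegression(
        slope=float(b1), intercept=float(b0),
        r2=float(1.0 - rss / tss) if tss > 0 else float("nan"),
        rmse=float(np.sqrt(rss / n)),
        aic=float(2 * _K_PARAMS - 2 * loglik),
        bic=float(_K_PARAMS * np.log(n) - 2 * loglik),
        loglik=float(loglik),
        n_subjects=n,
    )
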
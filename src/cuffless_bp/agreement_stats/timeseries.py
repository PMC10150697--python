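"""Time-series tests: Diebold-Mariano, augmented Dickey-Fuller, Fisher.

The Diebold-Mariano test compares two forecast-error sequences through the
mean loss differential d_t = L(e_a,t) - L(e_b,t), studentized with a
Newey-West (Bartlett-kernel) HAC variance and referred to the standard
normal.  Stationarity of error series is probed with the augmented
Dickey-Fuller test (constant-only regression, lag order by AIC; no trend
term — callers analysing trending series should note this).  Independent
p-values are combined with Fisher's method: X = -2 * sum(ln p) ~ chi2(2k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from ..exceptions import InsufficientDataError

_LOSSES = {
    "squared": lambda e: np.asarray(e, float) ** 2,
    "absolute": lambda e: np.abs(np.asarray(e, float)),
}


@dataclass
class DMResult:
    stat: float
    p: float
    lag: int
    loss: str
    degenerate: bool = False


def dm_test(errors_a, errors_b, *, loss: str = "squared", lag: int | None = None) -> DMResult:
    """Diebold-Mariano predictive-accuracy test on two error series.

    Negative statistic favours model a (smaller loss).  Both series must be
    time-ordered and equally long (>= 10).  Degenerate differentials are
    resolved by convention: d identically 0 -> (stat 0, p 1); d constant and
    nonzero -> p 0 with the ``degenerate`` flag set.
    """
    if loss not in _LOSSES:
        raise InsufficientDataError(f"loss must be one of {sorted(_LOSSES)}")
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape:
        raise InsufficientDataError("error series must have equal length")
    T = len(a)
    if T < 10:
        raise InsufficientDataError("need >= 10 observations for the DM test")
    d = _LOSSES[loss](a) - _LOSSES[loss](b)
    h = int(np.floor(T ** (1.0 / 3.0))) if lag is None else int(lag)
    h = max(h, 0)
    dbar = d.mean()
    dc = d - dbar
    if np.all(d == 0.0):
        return DMResult(stat=0.0, p=1.0, lag=h, loss=loss)
    gamma0 = float(dc @ dc) / T
    var = gamma0
    for j in range(1, min(h, T - 1) + 1):
        gj = float(dc[j:] @ dc[:-j]) / T
        var += 2.0 * (1.0 - j / (h + 1.0)) * gj
    if var <= 0:
        var = gamma0
    if var <= 0:
        # constant nonzero differential: one model dominates with certainty
        return DMResult(stat=float(np.sign(dbar) * np.inf), p=0.0, lag=h,
                        loss=loss, degenerate=True)
    stat = float(dbar / np.sqrt(var / T))
    return DMResult(stat=stat, p=float(2.0 * stats.norm.sf(abs(stat))), lag=h, loss=loss)


@dataclass
class ADFResult:
    stat: float
    p: float
    used_lag: int
    regression: str = "c"


def adf_test(series) -> ADFResult:
    """Augmented Dickey-Fuller unit-root test (constant-only regression,
    lag order by AIC, MacKinnon response-surface p-value)."""
    x = np.asarray(series, float)
    if len(x) < 20:
        raise InsufficientDataError("need >= 20 observations for the ADF test")
    if np.ptp(x) == 0:
        raise InsufficientDataError("ADF test undefined for a constant series")
    stat, p, used_lag, *_ = adfuller(x, regression="c", autolag="AIC")
    return ADFResult(stat=float(stat), p=float(p), used_lag=int(used_lag))


@dataclass
class FisherResult:
    chi2: float
    df: int
    p: float


def fisher_combine(p_values) -> FisherResult:
    """Fisher's method: X = -2 sum(ln p_i) ~ chi-square with 2k df."""
    ps = np.asarray(list(p_values), float)
    if len(ps) < 1:
        raise InsufficientDataError("need at least one p-value")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise InsufficientDataError(
            "p-values must lie in (0, 1]; floor exact zeros at machine "
            "epsilon explicitly before combining")
    x = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return FisherResult(chi2=x, df=df, p=float(stats.chi2.sf(x, df)))
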
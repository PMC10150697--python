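"""Full agreement summary per model and formal two-model comparison.

``summarize_pairs`` assembles every accuracy/agreement statistic for one
calibrated model against the reference (the full table of error metrics,
threshold percentages, pooled and repeated-measures Bland-Altman, rmcorr,
pooled Pearson and the aggregated-means regression).

``compare_models`` runs the three-step comparison between two models
evaluated on identical (subject, epoch) pairs:

1. error equality — Wilcoxon signed-rank on paired absolute errors — and an
   F-test of error-variance equality;
2. aggregated-means regressions compared numerically (R², RMSE, AIC, BIC);
3. Diebold-Mariano predictive accuracy, pooled and per subject with
   Fisher-combined p-values, plus ADF stationarity checks on each error
   series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..exceptions import InsufficientDataError
from .bland_altman import bland_altman_pooled, bland_altman_repeated
from .correlation import pearson_pooled, rmcorr
from .metrics import error_metrics, pct_within
from .pairs import check_pairs, errors, sort_pairs
from .regression import aggregated_regression
from .timeseries import adf_test, dm_test, fisher_combine

ALPHA = 0.05
_MIN_DM_SUBJECT_PAIRS = 10


@dataclass
class AgreementSummary:
    """All agreement statistics for one model on one BP component."""

    mean_error: float
    mae: float
    sd_mae: float
    sd_of_errors: float
    median_abs_error: float
    q1_abs_error: float
    q3_abs_error: float
    iqr_abs_error: float
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    ba_rm_bias: float
    ba_rm_loa_low: float
    ba_rm_loa_high: float
    rmcorr: float
    pearson_pooled: float
    agg_r2: float
    agg_rmse: float
    aic: float
    bic: float
    n_pairs: int
    n_subjects: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_pairs(pairs: pd.DataFrame) -> AgreementSummary:
    """Compute the full agreement summary; statistics whose preconditions the
    data cannot meet (e.g. < 4 subjects for the aggregated regression) are
    reported as NaN rather than failing the whole summary."""
    check_pairs(pairs, min_rows=3)
    m = error_metrics(pairs)
    pw = pct_within(pairs)
    ba = bland_altman_pooled(pairs, with_scatter=False)

    def _try(fn, *a, **k):
        try:
            return fn(*a, **k)
        except InsufficientDataError:
            return None

    ba_rm = _try(bland_altman_repeated, pairs)
    rc = _try(rmcorr, pairs)
    pr = _try(pearson_pooled, pairs)
    agg = _try(aggregated_regression, pairs)
    nan = float("nan")
    return AgreementSummary(
        mean_error=m["mean_error"], mae=m["mae"], sd_mae=m["sd_mae"],
        sd_of_errors=m["sd_of_errors"], median_abs_error=m["median_abs_error"],
        q1_abs_error=m["q1_abs_error"], q3_abs_error=m["q3_abs_error"],
        iqr_abs_error=m["iqr_abs_error"],
        pct_within_5=pw[5.0], pct_within_10=pw[10.0], pct_within_15=pw[15.0],
        ba_bias=ba.bias, ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high,
        ba_rm_bias=ba_rm.bias if ba_rm else nan,
        ba_rm_loa_low=ba_rm.loa_low if ba_rm else nan,
        ba_rm_loa_high=ba_rm.loa_high if ba_rm else nan,
        rmcorr=rc.r if rc else nan,
        pearson_pooled=pr if pr is not None else nan,
        agg_r2=agg.r2 if agg else nan, agg_rmse=agg.rmse if agg else nan,
        aic=agg.aic if agg else nan, bic=agg.bic if agg else nan,
        n_pairs=m["n_pairs"], n_subjects=int(pairs["subject_id"].nunique()),
    )


@dataclass
class ModelComparison:
    label_a: str
    label_b: str
    mae_a: float
    mae_b: float
    p_abs_error_equality: float
    p_variance_equality: float
    dm_stat_pooled: float
    p_dm_pooled: float
    per_subject_dm_p: dict = field(default_factory=dict)
    fisher_chi2: float = float("nan")
    fisher_df: int = 0
    p_fisher: float = float("nan")
    adf_p: dict = field(default_factory=dict)
    verdict: str = ""
    n_pairs: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["per_subject_dm_p"] = {k: float(v) for k, v in self.per_subject_dm_p.items()}
        d["adf_p"] = {k: float(v) for k, v in self.adf_p.items()}
        return d


def _wilcoxon_paired_abs(ae_a: np.ndarray, ae_b: np.ndarray) -> float:
    diff = ae_a - ae_b
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(ae_a, ae_b, zero_method="wilcox").pvalue)


def _variance_f_test(e_a: np.ndarray, e_b: np.ndarray) -> float:
    va, vb = e_a.var(ddof=1), e_b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(e_a) - 1, len(e_b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def compare_models(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    *,
    label_a: str = "generalized",
    label_b: str = "individualized",
    loss: str = "squared",
    alpha: float = ALPHA,
) -> ModelComparison:
    """Three-step statistical comparison of two models on shared epochs."""
    check_pairs(pairs_a, min_rows=3)
    check_pairs(pairs_b, min_rows=3)
    a = sort_pairs(pairs_a)
    b = sort_pairs(pairs_b)
    keys_a = list(zip(a["subject_id"], a["epoch_start"]))
    keys_b = list(zip(b["subject_id"], b["epoch_start"]))
    if keys_a != keys_b:
        raise InsufficientDataError(
            "the two models must be evaluated on identical (subject, epoch) pairs")

    e_a, e_b = errors(a), errors(b)
    ae_a, ae_b = np.abs(e_a), np.abs(e_b)
    p_eq = _wilcoxon_paired_abs(ae_a, ae_b)
    p_var = _variance_f_test(e_a, e_b)
    dm_pooled = dm_test(e_a, e_b, loss=loss)

    per_subject: dict[str, float] = {}
    for sid, grp in a.groupby("subject_id", sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < _MIN_DM_SUBJECT_PAIRS:
            continue
        res = dm_test(e_a[idx], e_b[idx], loss=loss)
        per_subject[str(sid)] = res.p
    if per_subject:
        floored = np.clip(list(per_subject.values()), 1e-300, 1.0)
        fish = fisher_combine(floored)
        fisher_chi2, fisher_df, p_fisher = fish.chi2, fish.df, fish.p
    else:
        fisher_chi2, fisher_df, p_fisher = float("nan"), 0, float("nan")

    adf_p = {}
    for label, e in ((label_a, e_a), (label_b, e_b)):
        try:
            adf_p[label] = adf_test(e).p
        except InsufficientDataError:
            adf_p[label] = float("nan")

    mae_a, mae_b = float(ae_a.mean()), float(ae_b.mean())
    better = label_b if mae_b < mae_a else label_a
    sig = "significantly" if dm_pooled.p < alpha else "non-significantly"
    verdict = f"{better} model is {sig} better"

    return ModelComparison(
        label_a=label_a, label_b=label_b, mae_a=mae_a, mae_b=mae_b,
        p_abs_error_equality=p_eq, p_variance_equality=p_var,
        dm_stat_pooled=dm_pooled.stat, p_dm_pooled=dm_pooled.p,
        per_subject_dm_p=per_subject, fisher_chi2=fisher_chi2,
        fisher_df=fisher_df, p_fisher=p_fisher, adf_p=adf_p,
        verdict=verdict, n_pairs=len(a),
    )
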
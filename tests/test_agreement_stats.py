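"""Agreement-statistics suite: frozen hand-computed examples, Monte-Carlo
recoveries and cross-checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuffless_bp.agreement_stats import (
    adf_test,
    aggregated_regression,
    bland_altman_pooled,
    bland_altman_repeated,
    dm_test,
    error_metrics,
    fisher_combine,
    make_pairs,
    pct_within,
    pearson_pooled,
    rmcorr,
)
from cuffless_bp.exceptions import InsufficientDataError


def _pairs(ref, est, sid="s0"):
    ref = np.asarray(ref, float)
    return make_pairs([sid] * len(ref), np.arange(len(ref)) * 15.0, ref, est)


# ------------------------------------------------------------- metrics


def test_error_metrics_hand_example():
    m = error_metrics(_pairs([120, 130, 110], [118, 135, 110]))
    assert m["mean_error"] == pytest.approx(1.0)
    assert m["mae"] == pytest.approx(7.0 / 3.0)
    assert m["sd_of_errors"] == pytest.approx(np.sqrt(13.0))


def test_error_metrics_degenerate_cases():
    ref = np.linspace(100, 140, 10)
    assert error_metrics(_pairs(ref, ref))["mae"] == 0.0
    m = error_metrics(_pairs(ref, ref + 5))
    assert m["mean_error"] == pytest.approx(5.0)
    assert m["mae"] == pytest.approx(5.0)
    assert m["sd_of_errors"] == pytest.approx(0.0, abs=1e-12)


def test_pct_within_counting():
    ref = np.zeros(4)
    est = np.array([4.0, 6.0, 12.0, 20.0])
    pw = pct_within(_pairs(ref, est))
    assert pw[5.0] == 25.0 and pw[10.0] == 50.0 and pw[15.0] == 75.0
    pw_all = pct_within(_pairs([0, 0, 0], [-2.0, 5.0, 0.0]))
    assert pw_all[5.0] == 100.0


def test_pct_within_thresholds_validated():
    p = _pairs([0, 0], [1, 1])
    with pytest.raises(InsufficientDataError):
        pct_within(p, thresholds=[])
    with pytest.raises(InsufficientDataError):
        pct_within(p, thresholds=[10, 5])


# --------------------------------------------------------- Bland-Altman


def test_bland_altman_pooled_hand_example():
    ba = bland_altman_pooled(_pairs([0, 0, 0], [-2.0, 5.0, 0.0]))
    assert ba.bias == pytest.approx(1.0)
    assert ba.loa_low == pytest.approx(1.0 - 1.96 * np.sqrt(13.0), abs=1e-6)
    assert ba.loa_high == pytest.approx(1.0 + 1.96 * np.sqrt(13.0), abs=1e-6)
    assert ba.loa_low < ba.bias < ba.loa_high


def test_bland_altman_perfect_agreement():
    ref = np.linspace(90, 110, 5)
    ba = bland_altman_pooled(_pairs(ref, ref))
    assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0


def test_bland_altman_repeated_degenerate_matches_pooled():
    """With zero between-subject heterogeneity the repeated-measures LOA
    converge to the pooled LOA."""
    rng = np.random.default_rng(1)
    sid = np.repeat([f"s{k}" for k in range(10)], 200)
    e = rng.normal(0, 4, 2000)
    pairs = make_pairs(sid, np.tile(np.arange(200) * 15.0, 10), np.zeros(2000), e)
    pooled = bland_altman_pooled(pairs)
    rep = bland_altman_repeated(pairs)
    assert rep.sd == pytest.approx(pooled.sd, rel=0.01)
    assert abs(rep.loa_high - pooled.loa_high) < 1.0


def test_bland_altman_repeated_recovers_variance_components():
    rng = np.random.default_rng(5)
    sid, t, est = [], [], []
    for s in range(25):
        b = rng.normal(0, 5)
        e = b + rng.normal(0, 3, 100)
        sid += [f"s{s:02d}"] * 100
        t += list(np.arange(100) * 15.0)
        est += list(e)
    pairs = make_pairs(sid, t, np.zeros(2500), est)
    rep = bland_altman_repeated(pairs)
    assert rep.sd == pytest.approx(np.sqrt(34.0), rel=0.10)


def test_bland_altman_repeated_rejects_single_subject():
    pairs = _pairs(np.zeros(10), np.arange(10.0))
    with pytest.raises(InsufficientDataError, match="pooled"):
        bland_altman_repeated(pairs)


# ------------------------------------------------------------ correlation


def test_rmcorr_perfect_within_subject_lines():
    sid, t, ref, est = [], [], [], []
    for s, intercept in enumerate([0.0, 50.0, -30.0]):
        x = np.linspace(100, 130, 20)
        sid += [f"s{s}"] * 20
        t += list(np.arange(20) * 15.0)
        ref += list(x)
        est += list(2.0 * x + intercept)
    r = rmcorr(make_pairs(sid, t, ref, est))
    assert r.r == pytest.approx(1.0)


def test_rmcorr_immune_to_confounded_subject_means():
    """Within-subject correlation 0 but strongly correlated subject means:
    rmcorr ~ 0 while the pooled Pearson is large — the reason rmcorr exists."""
    rng = np.random.default_rng(4)
    sid, t, ref, est = [], [], [], []
    for s in range(25):
        m = rng.normal(0, 10)
        sid += [f"s{s:02d}"] * 200
        t += list(np.arange(200) * 15.0)
        ref += list(m + rng.standard_normal(200))
        est += list(m + rng.standard_normal(200))
    pairs = make_pairs(sid, t, ref, est)
    assert abs(rmcorr(pairs).r) < 0.05
    assert pearson_pooled(pairs) > 0.8


def test_rmcorr_offset_invariance():
    rng = np.random.default_rng(9)
    sid = np.repeat([f"s{k}" for k in range(5)], 50)
    ref = rng.normal(100, 5, 250)
    est = ref + rng.normal(0, 3, 250)
    t = np.tile(np.arange(50) * 15.0, 5)
    base = rmcorr(make_pairs(sid, t, ref, est)).r
    offsets = np.repeat(rng.normal(0, 40, 5), 50)
    shifted = rmcorr(make_pairs(sid, t, ref, est + offsets)).r
    assert shifted == pytest.approx(base, abs=1e-12)


def test_rmcorr_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    sid = np.repeat([f"s{k}" for k in range(8)], 30)
    ref = rng.normal(100, 8, 240)
    est = 0.6 * ref + rng.normal(0, 5, 240) + np.repeat(rng.normal(0, 10, 8), 30)
    pairs = make_pairs(sid, np.tile(np.arange(30) * 15.0, 8), ref, est)
    ours = rmcorr(pairs)
    df = pd.DataFrame({"subject": sid, "x": ref, "y": est})
    ref_res = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
    assert ours.r == pytest.approx(float(ref_res["r"].iloc[0]), abs=1e-6)
    assert ours.df == int(ref_res["dof"].iloc[0])


def test_pearson_pooled_signs():
    ref = np.linspace(90, 130, 20)
    assert pearson_pooled(_pairs(ref, ref)) == pytest.approx(1.0)
    assert pearson_pooled(_pairs(ref, -ref)) == pytest.approx(-1.0)
    with pytest.raises(InsufficientDataError):
        pearson_pooled(_pairs(np.full(5, 100.0), np.arange(5.0)))


# ----------------------------------------------------- aggregated means


def test_aggregated_regression_perfect_fit():
    sid = np.repeat([f"s{k}" for k in range(5)], 10)
    ref = np.repeat([100.0, 110.0, 120.0, 130.0, 140.0], 10)
    pairs = make_pairs(sid, np.tile(np.arange(10) * 15.0, 5), ref, ref)
    agg = aggregated_regression(pairs)
    assert agg.r2 == pytest.approx(1.0)
    assert agg.rmse == pytest.approx(0.0, abs=1e-9)


def test_aggregated_regression_matches_statsmodels_loglik():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    means_est = np.array([100.0, 108.0, 117.0, 126.0, 140.0])
    means_ref = means_est + rng.normal(0, 3, 5)
    sid, t, ref, est = [], [], [], []
    for k, (mr, me) in enumerate(zip(means_ref, means_est)):
        sid += [f"s{k}"] * 4
        t += list(np.arange(4) * 15.0)
        ref += [mr] * 4
        est += [me] * 4
    agg = aggregated_regression(make_pairs(sid, t, ref, est))
    fit = sm.OLS(means_ref, sm.add_constant(means_est)).fit()
    assert agg.r2 == pytest.approx(fit.rsquared, abs=1e-9)
    assert agg.loglik == pytest.approx(fit.llf, abs=1e-6)
    assert agg.aic == pytest.approx(2 * 3 - 2 * fit.llf, abs=1e-6)
    assert agg.bic == pytest.approx(3 * np.log(5) - 2 * fit.llf, abs=1e-6)


def test_aggregated_regression_degrades_with_noise():
    rng = np.random.default_rng(12)
    r2s = []
    for noise in (0.0, 3.0, 9.0):
        vals = []
        for rep in range(100):
            means_ref = np.linspace(100, 140, 8)
            means_est = means_ref + rng.normal(0, noise + 1e-9, 8)
            sid = [f"s{k}" for k in range(8)]
            pairs = make_pairs(np.repeat(sid, 2), np.tile([0.0, 15.0], 8),
                               np.repeat(means_ref, 2), np.repeat(means_est, 2))
            vals.append(aggregated_regression(pairs).r2)
        r2s.append(np.mean(vals))
    assert r2s[0] > r2s[1] > r2s[2]


def test_aggregated_regression_needs_four_subjects():
    sid = np.repeat(["a", "b", "c"], 5)
    pairs = make_pairs(sid, np.tile(np.arange(5) * 15.0, 3),
                       np.arange(15.0) + 100, np.arange(15.0) + 101)
    with pytest.raises(InsufficientDataError):
        aggregated_regression(pairs)


# --------------------------------------------------------- time series


def test_dm_identical_series():
    e = np.random.default_rng(0).standard_normal(50)
    res = dm_test(e, e.copy())
    assert res.stat == 0.0 and res.p == 1.0


def test_dm_detects_dominated_model():
    rng = np.random.default_rng(1)
    e = rng.standard_normal(500)
    res = dm_test(e, 2.0 * e)
    assert res.p < 0.01
    assert res.stat < 0  # negative: model a has smaller loss


def test_dm_length_mismatch_rejected():
    with pytest.raises(InsufficientDataError):
        dm_test(np.zeros(20), np.zeros(21))


def test_dm_absolute_loss_supported():
    rng = np.random.default_rng(2)
    res = dm_test(rng.standard_normal(200), rng.standard_normal(200),
                  loss="absolute")
    assert 0.0 <= res.p <= 1.0


def test_adf_rejects_unit_root_for_white_noise():
    rng = np.random.default_rng(3)
    hits = sum(adf_test(rng.standard_normal(500)).p < 0.05 for _ in range(20))
    assert hits >= 19


def test_adf_keeps_unit_root_for_random_walk():
    rng = np.random.default_rng(4)
    keeps = sum(adf_test(np.cumsum(rng.standard_normal(500))).p > 0.05
                for _ in range(20))
    assert keeps >= 18


def test_adf_constant_series_rejected():
    with pytest.raises(InsufficientDataError):
        adf_test(np.full(100, 3.0))


def test_fisher_hand_examples():
    res = fisher_combine([1.0, 1.0, 1.0])
    assert res.chi2 == 0.0 and res.p == pytest.approx(1.0)
    res = fisher_combine([0.5, 0.5])
    assert res.chi2 == pytest.approx(-2 * np.log(0.25), abs=1e-9)
    assert res.df == 4
    # closed form for df=4: p = e^{-x/2} (1 + x/2)
    x = res.chi2
    assert res.p == pytest.approx(np.exp(-x / 2) * (1 + x / 2), abs=1e-12)


def test_fisher_rejects_zero_pvalue():
    with pytest.raises(InsufficientDataError):
        fisher_combine([0.0, 0.5])


def test_fisher_matches_scipy():
    ps = [0.01, 0.2, 0.8, 0.33]
    ours = fisher_combine(ps)
    ref = stats.combine_pvalues(ps, method="fisher")
    assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-12)
    assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


# -------------------------------------------- order/relabel invariance


def test_statistics_invariant_to_subject_relabeling_and_row_order():
    rng = np.random.default_rng(6)
    sid = np.repeat([f"s{k}" for k in range(6)], 40)
    ref = rng.normal(110, 8, 240)
    est = ref + rng.normal(0, 4, 240)
    t = np.tile(np.arange(40) * 15.0, 6)
    pairs = make_pairs(sid, t, ref, est)
    perm = rng.permutation(240)
    shuffled = pairs.iloc[perm].reset_index(drop=True)
    relabeled = shuffled.assign(
        subject_id=shuffled["subject_id"].map(lambda s: "x" + s[::-1]))
    for fn in (lambda p: error_metrics(p)["mae"],
               lambda p: bland_altman_pooled(p).loa_high,
               lambda p: rmcorr(p).r,
               pearson_pooled,
               lambda p: aggregated_regression(p).r2):
        assert fn(relabeled) == pytest.approx(fn(pairs), abs=1e-12)
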
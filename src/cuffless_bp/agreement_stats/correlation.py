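"""Correlation measures: repeated-measures correlation and pooled Pearson.

The repeated-measures correlation (rmcorr) is the analysis-of-covariance
estimator: subject means are removed from both variables and the residuals
correlated, so the coefficient reflects the common *within-subject*
association and is immune to between-subject offsets.  Pooling all pairs
into a single Pearson correlation is also provided — not as an accuracy
measure but because comparable studies report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..exceptions import InsufficientDataError
from .pairs import check_pairs


@dataclass
class RmCorr:
    r: float
    df: int
    p: float


def rmcorr(pairs: pd.DataFrame, *, min_pairs_per_subject: int = 3) -> RmCorr:
    """Within-subject correlation of estimate vs reference.

    Subjects need >= ``min_pairs_per_subject`` pairs; a subject whose
    reference is constant after centering simply contributes zero weight.
    Degrees of freedom are N - n_subjects - 1.
    """
    check_pairs(pairs, min_rows=4)
    kept = pairs.groupby("subject_id").filter(lambda g: len(g) >= min_pairs_per_subject)
    n_subj = kept["subject_id"].nunique()
    if n_subj < 2:
        raise InsufficientDataError(
            f"rmcorr needs >= 2 subjects with >= {min_pairs_per_subject} pairs")
    g = kept.groupby("subject_id")
    x = kept["reference"] - g["reference"].transform("mean")
    y = kept["estimate"] - g["estimate"].transform("mean")
    sxx = float((x ** 2).sum())
    syy = float((y ** 2).sum())
    if sxx <= 0 or syy <= 0:
        raise InsufficientDataError("no within-subject variation in one of the variables")
    r = float((x * y).sum() / np.sqrt(sxx * syy))
    df = int(len(kept) - n_subj - 1)
    if df <= 0:
        raise InsufficientDataError("not enough pairs for rmcorr degrees of freedom")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return RmCorr(r=r, df=df, p=p)


def pearson_pooled(pairs: pd.DataFrame) -> float:
    """Product-moment correlation over all pairs pooled across subjects."""
    check_pairs(pairs, min_rows=3)
    ref = pairs["reference"].to_numpy(float)
    est = pairs["estimate"].to_numpy(float)
    if ref.std() == 0 or est.std() == 0:
        raise InsufficientDataError("pooled Pearson undefined for zero-variance input")
    return float(stats.pearsonr(ref, est).statistic)
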
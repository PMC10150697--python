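"""Bland-Altman agreement: pooled and repeated-measures variants.

The pooled variant treats all pairs as independent (the convention in
comparable device studies, kept for comparability).  The repeated-measures
variant decomposes the variance of the differences into between-subject and
within-subject components with a one-way random-effects ANOVA (unbalanced
designs handled via the standard n0 correction) so the limits of agreement
are not narrowed by within-subject clustering.  With no between-subject
heterogeneity the two variants coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import InsufficientDataError
from .pairs import check_pairs, errors

Z_95 = 1.96


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float                 # SD entering the LOA
    method: str               # "pooled" | "repeated"
    n_pairs: int
    n_subjects: int
    scatter: pd.DataFrame | None = None   # mean, difference, subject_id


def bland_altman_pooled(pairs: pd.DataFrame, *, with_scatter: bool = True) -> BlandAltman:
    """bias = mean difference; LOA = bias +/- 1.96 * SD of differences."""
    check_pairs(pairs, min_rows=3)
    d = errors(pairs)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    scatter = None
    if with_scatter:
        scatter = pd.DataFrame({
            "mean": (pairs["reference"].to_numpy() + pairs["estimate"].to_numpy()) / 2.0,
            "difference": d,
            "subject_id": pairs["subject_id"].to_numpy(),
        })
    return BlandAltman(
        bias=bias, loa_low=bias - Z_95 * sd, loa_high=bias + Z_95 * sd,
        sd=sd, method="pooled", n_pairs=len(d),
        n_subjects=int(pairs["subject_id"].nunique()), scatter=scatter,
    )


def bland_altman_repeated(pairs: pd.DataFrame) -> BlandAltman:
    """Repeated-measures LOA via one-way variance components on differences."""
    check_pairs(pairs, min_rows=4)
    groups = [g.to_numpy(float) for _, g in
              (pairs["estimate"] - pairs["reference"]).groupby(pairs["subject_id"])]
    sizes = np.array([len(g) for g in groups])
    if len(groups) < 2 or np.any(sizes < 2):
        raise InsufficientDataError(
            "repeated-measures LOA needs >= 2 subjects with >= 2 pairs each; "
            "use bland_altman_pooled for a single subject")
    d = errors(pairs)
    N, k = int(sizes.sum()), len(groups)
    grand = d.mean()
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ssb = float((sizes * (means - grand) ** 2).sum())
    msw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - (sizes ** 2).sum() / N) / (k - 1)
    var_between = max((msb - msw) / n0, 0.0)
    total_sd = float(np.sqrt(var_between + msw))
    bias = float(grand)
    return BlandAltman(
        bias=bias, loa_low=bias - Z_95 * total_sd, loa_high=bias + Z_95 * total_sd,
        sd=total_sd, method="repeated", n_pairs=N, n_subjects=k,
    )
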
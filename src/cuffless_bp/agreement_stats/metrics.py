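"""Error metrics and threshold percentages (Table-style accuracy rows)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import InsufficientDataError
from .pairs import check_pairs, errors


def error_metrics(pairs: pd.DataFrame) -> dict:
    """Mean error, MAE (with SD of absolute errors), SD of errors, and the
    median/IQR of absolute errors, all in mmHg.

    ``sd_mae`` is the SD of the |error| distribution (the parenthetical SD
    printed next to MAE in accuracy tables); ``sd_of_errors`` is the SD of
    the signed errors.  Sample SDs use the n-1 denominator.
    """
    check_pairs(pairs, min_rows=1)
    e = errors(pairs)
    ae = np.abs(e)
    q1, q3 = np.percentile(ae, [25, 75])
    return {
        "mean_error": float(e.mean()),
        "mae": float(ae.mean()),
        "sd_mae": float(ae.std(ddof=1)) if len(ae) > 1 else 0.0,
        "sd_of_errors": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
        "median_abs_error": float(np.median(ae)),
        "q1_abs_error": float(q1),
        "q3_abs_error": float(q3),
        "iqr_abs_error": float(q3 - q1),
        "n_pairs": int(len(e)),
    }


def pct_within(pairs: pd.DataFrame, thresholds=(5.0, 10.0, 15.0)) -> dict:
    """Percentage of absolute errors <= each threshold (inclusive)."""
    thresholds = list(thresholds)
    if len(thresholds) == 0:
        raise InsufficientDataError("thresholds must be nonempty")
    if any(t <= 0 for t in thresholds) or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise InsufficientDataError("thresholds must be positive and ascending")
    check_pairs(pairs, min_rows=1)
    ae = np.abs(errors(pairs))
    return {float(t): float(100.0 * np.mean(ae <= t)) for t in thresholds}
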
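"""PPG pulse-morphology features.

Features are computed per beat from the PPG window starting at the detected
pulse foot.  They are the "other signal features" available to
subject-specific models beyond PAT and HR:

========  =====================================================  =======
feature   definition                                             units
========  =====================================================  =======
amplitude peak minus baseline (window minimum before the peak)   a.u.
rise_time foot-to-peak time                                      ms
width_50  duration above half amplitude                          ms
pulse_area  integral of (signal - baseline) over the window      a.u.*s
reflection_ratio  late-systolic (dicrotic) height / amplitude    --
========  =====================================================  =======
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

MORPH_FEATURES = ("amplitude", "rise_time", "width_50", "pulse_area", "reflection_ratio")
FEATURE_NAMES = ("pat", "hr") + MORPH_FEATURES

_FLAT_EPS = 1e-6
_DICROTIC_WINDOW = (0.45, 0.65)   # fraction of the beat window


def extract_ppg_features(
    window: np.ndarray,
    fs: float,
    *,
    pat_ms: float = math.nan,
    hr_bpm: float = math.nan,
) -> dict | None:
    """Morphology features for one PPG beat window (foot to next foot).

    Returns ``None`` for flat/degenerate windows (the beat is then marked
    invalid by the caller).  ``pat_ms``/``hr_bpm`` are passed through so the
    result is the complete per-beat feature dict.
    """
    x = np.asarray(window, float)
    n = len(x)
    if n < 5:
        return None
    peak_i = int(np.argmax(x))
    base_i = int(np.argmin(x[: peak_i + 1]))
    baseline = float(x[base_i])
    amplitude = float(x[peak_i] - baseline)
    if amplitude < _FLAT_EPS or peak_i == 0:
        return None
    half = baseline + 0.5 * amplitude
    above = x >= half
    # contiguous half-height region around the main peak
    lo = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    d0, d1 = int(_DICROTIC_WINDOW[0] * n), max(int(_DICROTIC_WINDOW[1] * n), int(_DICROTIC_WINDOW[0] * n) + 1)
    dicrotic = float(np.max(x[d0:d1]) - baseline) if d1 <= n else float("nan")
    return {
        "pat": float(pat_ms),
        "hr": float(hr_bpm),
        "amplitude": amplitude,
        "rise_time": (peak_i - base_i) / fs * 1000.0,
        "width_50": (hi - lo + 1) / fs * 1000.0,
        "pulse_area": float(np.sum(x - baseline)) / fs,
        "reflection_ratio": dicrotic / amplitude,
    }


def beat_morphology(
    ppg: np.ndarray,
    fs: float,
    foot_times: np.ndarray,
    pat_ms: np.ndarray,
    hr_bpm: np.ndarray,
) -> pd.DataFrame:
    """Per-beat feature table; NaN rows for beats without a usable pulse."""
    ppg = np.asarray(ppg, float)
    foot_times = np.asarray(foot_times, float)
    n = len(foot_times)
    out = {name: np.full(n, np.nan) for name in FEATURE_NAMES}
    for i in range(n):
        f0 = foot_times[i]
        if not np.isfinite(f0):
            continue
        f1 = foot_times[i + 1] if i + 1 < n and np.isfinite(foot_times[i + 1]) else None
        if f1 is None:
            # fall back to RR implied by HR for the final/unpaired beat
            rr = 60.0 / hr_bpm[i] if np.isfinite(hr_bpm[i]) and hr_bpm[i] > 0 else None
            f1 = f0 + rr if rr else None
        if f1 is None:
            continue
        i0, i1 = int(round(f0 * fs)), min(int(round(f1 * fs)), len(ppg))
        feats = extract_ppg_features(ppg[i0:i1], fs, pat_ms=pat_ms[i], hr_bpm=hr_bpm[i])
        if feats is None:
            continue
        for name in FEATURE_NAMES:
            out[name][i] = feats[name]
    return pd.DataFrame(out)
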
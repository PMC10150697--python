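"""ECG R-peak and PPG pulse-foot detection.

The R-peak detector is Pan-Tompkins-style: zero-phase band-pass (5-25 Hz),
squared energy, short moving-average envelope, block-adaptive threshold and
a 200 ms refractory period, with the final peak location refined on the raw
signal.  The PPG foot is located by intersecting tangents: the tangent at
the maximum-slope point of the rising edge is intersected with the level of
the preceding minimum.  Both return times in seconds; the foot is estimated
with sub-sample precision.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from ..exceptions import InsufficientDataError, InvalidRecordError

REFRACTORY_S = 0.2
_BAND_HZ = (5.0, 25.0)
_BLOCK_S = 8.0
FOOT_WINDOW_FRAC = 0.6   # feet searched in (r, r + 0.6*RR)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) in a single-channel ECG.

    A flat (or empty-looking) signal yields an empty array, not an error.
    """
    ecg = np.asarray(ecg, float)
    if len(ecg) < 2 * fs:
        raise InsufficientDataError("need at least 2 s of ECG")
    nyq = fs / 2.0
    b, a = butter(2, [_BAND_HZ[0] / nyq, min(_BAND_HZ[1], 0.45 * fs) / nyq], btype="band")
    filt = filtfilt(b, a, ecg)
    energy = uniform_filter1d(filt * filt, max(int(0.12 * fs), 1))
    if not np.isfinite(energy).all() or energy.max() < 1e-9:
        return np.array([])

    # block-adaptive threshold: robust to localized noise bursts
    block = max(int(_BLOCK_S * fs), 1)
    n_blocks = int(np.ceil(len(energy) / block))
    p99 = np.array([
        np.percentile(energy[k * block:(k + 1) * block], 99) for k in range(n_blocks)
    ])
    floor = 0.10 * np.median(p99)
    thr = np.repeat(np.maximum(0.35 * p99, floor), block)[: len(energy)]

    peaks, _ = find_peaks(energy, height=thr, distance=max(int(REFRACTORY_S * fs), 1))
    if len(peaks) == 0:
        return np.array([])
    # refine on the raw waveform (zero-phase chain keeps alignment)
    half = int(0.04 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= REFRACTORY_S * fs:
            keep.append(r)
    return np.asarray(keep, float) / fs


def detect_ppg_feet(ppg: np.ndarray, fs: float, r_times: np.ndarray) -> np.ndarray:
    """Pulse-foot time for each R peak via intersecting tangents.

    Returns one (possibly NaN) foot time per R peak; a foot is only accepted
    inside (r, r + 0.6*RR).  Missing/flat pulses give NaN (invalid beats).
    """
    r_times = np.asarray(r_times, float)
    if len(r_times) == 0:
        raise InsufficientDataError("r_times must be nonempty")
    ppg = np.asarray(ppg, float)
    smooth = gaussian_filter1d(ppg, max(0.006 * fs, 0.5))
    deriv = np.gradient(smooth) * fs

    rr = np.empty_like(r_times)
    if len(r_times) > 1:
        rr[:-1] = np.diff(r_times)
        rr[-1] = rr[-2]
    else:
        rr[:] = 1.0

    feet = np.full(len(r_times), np.nan)
    n = len(ppg)
    for i, (r, rri) in enumerate(zip(r_times, rr)):
        i0 = int(np.ceil(r * fs)) + 1
        i1 = min(int((r + FOOT_WINDOW_FRAC * rri) * fs), n)
        if i1 - i0 < 4:
            continue
        seg = smooth[i0:i1]
        if seg.max() - seg.min() < 1e-6:
            continue   # flat window: nothing to detect
        j = i0 + int(np.argmax(deriv[i0:i1]))
        slope = deriv[j]
        if slope <= 0:
            continue
        base = float(np.min(smooth[i0:j + 1]))
        foot = j / fs - (smooth[j] - base) / slope
        if r < foot < r + FOOT_WINDOW_FRAC * rri:
            feet[i] = foot
    return feet
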
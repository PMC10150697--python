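"""Per-beat series: PAT/HR pairing, reference BP extraction and the
automatic arterial artifact filter."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..exceptions import InvalidRecordError

# invalid-beat reason codes
R_NO_FOOT = "no_foot"
R_NEGATIVE_PAT = "negative_pat"
R_PAT_EXCEEDS_RR = "pat_exceeds_rr"
R_NO_RR = "no_rr"
R_SBP_RANGE = "sbp_out_of_range"
R_DBP_RANGE = "dbp_out_of_range"
R_LOW_PP = "low_pulse_pressure"
R_SBP_JUMP = "sbp_jump"
R_MAP_RANGE = "map_out_of_range"

SBP_LIMITS = (40.0, 300.0)
DBP_LIMITS = (20.0, 200.0)
MIN_PULSE_PRESSURE = 10.0
MAX_SBP_JUMP = 30.0       # mmHg between consecutive valid beats
JUMP_MEMORY_S = 5.0       # re-anchor the jump filter after this gap


@dataclass
class BeatSeries:
    """Aligned per-beat fiducials, intervals, BP and validity."""

    r_time: np.ndarray          # s
    ppg_foot_time: np.ndarray   # s (NaN when no foot)
    pat: np.ndarray             # ms
    rr: np.ndarray              # s
    hr: np.ndarray              # bpm
    sbp: np.ndarray = field(default=None)
    dbp: np.ndarray = field(default=None)
    map: np.ndarray = field(default=None)
    valid: np.ndarray = field(default=None)
    invalid_reason: np.ndarray = field(default=None)
    features: pd.DataFrame | None = None   # per-beat PPG morphology

    def __post_init__(self):
        n = len(self.r_time)
        if self.valid is None:
            self.valid = np.ones(n, bool)
        if self.invalid_reason is None:
            self.invalid_reason = np.full(n, "", dtype=object)
        for name in ("sbp", "dbp", "map"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))

    def __len__(self) -> int:
        return len(self.r_time)

    def copy(self) -> "BeatSeries":
        return replace(
            self,
            **{k: getattr(self, k).copy() for k in
               ("r_time", "ppg_foot_time", "pat", "rr", "hr", "sbp", "dbp",
                "map", "valid", "invalid_reason")},
            features=None if self.features is None else self.features.copy(),
        )

    def mark_invalid(self, mask: np.ndarray, reason: str) -> None:
        mask = np.asarray(mask, bool) & self.valid
        self.valid[mask] = False
        self.invalid_reason[mask] = reason

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "r_time": self.r_time, "ppg_foot_time": self.ppg_foot_time,
            "pat": self.pat, "rr": self.rr, "hr": self.hr,
            "sbp": self.sbp, "dbp": self.dbp, "map": self.map,
            "valid": self.valid, "invalid_reason": self.invalid_reason,
        })
        if self.features is not None:
            for col in self.features.columns:
                if col not in df.columns:
                    df[col] = self.features[col].to_numpy()
        return df


def compute_pat_hr(r_times: np.ndarray, foot_times: np.ndarray) -> BeatSeries:
    """Pair fiducials into a BeatSeries with PAT (ms), RR (s) and HR (bpm).

    The final beat has no RR interval and is marked invalid (``no_rr``);
    feet before their R peak or beyond the RR interval invalidate the beat.
    """
    r_times = np.asarray(r_times, float)
    foot_times = np.asarray(foot_times, float)
    if len(r_times) != len(foot_times):
        raise InvalidRecordError("r_times and foot_times must be paired")
    if len(r_times) < 2:
        raise InvalidRecordError("need at least 2 beats")
    if np.any(np.diff(r_times) <= 0):
        raise InvalidRecordError("r_times must be strictly increasing")
    finite = np.isfinite(foot_times)
    if np.any(np.diff(foot_times[finite]) <= 0):
        raise InvalidRecordError("foot_times must be increasing where present")

    n = len(r_times)
    rr = np.empty(n)
    rr[:-1] = np.diff(r_times)
    rr[-1] = np.nan
    hr = 60.0 / rr
    pat = (foot_times - r_times) * 1000.0

    beats = BeatSeries(
        r_time=r_times, ppg_foot_time=foot_times, pat=pat, rr=rr, hr=hr,
    )
    beats.mark_invalid(np.isnan(rr), R_NO_RR)
    beats.mark_invalid(~finite, R_NO_FOOT)
    with np.errstate(invalid="ignore"):
        beats.mark_invalid(pat <= 0, R_NEGATIVE_PAT)
        beats.mark_invalid(pat >= rr * 1000.0, R_PAT_EXCEEDS_RR)
    return beats


def extract_beat_bp(art: np.ndarray, fs: float, beats: BeatSeries) -> BeatSeries:
    """Reference SBP/DBP/MAP per beat window [r_i, r_{i+1}) from the raw
    arterial waveform (max / min / time-average)."""
    art = np.asarray(art, float)
    if len(beats) == 0:
        raise InvalidRecordError("empty beat series")
    out = beats.copy()
    starts = np.clip((beats.r_time * fs).astype(int), 0, len(art) - 1)
    for i in range(len(beats) - 1):
        seg = art[starts[i]:starts[i + 1]]
        if len(seg) == 0:
            continue
        out.sbp[i] = seg.max()
        out.dbp[i] = seg.min()
        out.map[i] = seg.mean()
    return out


def filter_arterial_artifacts(beats: BeatSeries) -> BeatSeries:
    """Automatic artifact rules on the reference BP (flushes, flatlines,
    detachments, implausible ranges); updates the validity mask with reasons."""
    out = beats.copy()
    sbp, dbp, mapv = out.sbp, out.dbp, out.map
    with np.errstate(invalid="ignore"):
        out.mark_invalid((sbp < SBP_LIMITS[0]) | (sbp > SBP_LIMITS[1]), R_SBP_RANGE)
        out.mark_invalid((dbp < DBP_LIMITS[0]) | (dbp > DBP_LIMITS[1]), R_DBP_RANGE)
        out.mark_invalid(sbp - dbp < MIN_PULSE_PRESSURE, R_LOW_PP)
        out.mark_invalid((mapv <= dbp) | (mapv >= sbp), R_MAP_RANGE)
    # jump rule: compare each remaining beat to the previous valid one; the
    # anchor expires after JUMP_MEMORY_S so a single artifact beat that slips
    # through the range rules cannot invalidate the rest of the record
    prev = None
    for i in range(len(out)):
        if not out.valid[i]:
            continue
        if prev is not None and out.r_time[i] - out.r_time[prev] <= JUMP_MEMORY_S \
                and abs(sbp[i] - sbp[prev]) > MAX_SBP_JUMP:
            out.valid[i] = False
            out.invalid_reason[i] = R_SBP_JUMP
            continue
        prev = i
    return out
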
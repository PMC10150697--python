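"""Synthesis of synchronized ECG / PPG / arterial-pressure waveforms.

Templates are deliberately the simplest shapes that exercise every fiducial
detector downstream:

* ECG: Gaussian R wave with small Q/S side lobes on a flat baseline.
* PPG: asymmetric beta-shaped pulse (fast rise, slow decay) plus a Gaussian
  dicrotic bump whose relative height is the "reflection ratio".  The pulse
  is positioned so that its *intersecting-tangents foot* (the morphological
  landmark the foot detector estimates) lies exactly at R-peak time + PAT.
* Arterial: two-Gaussian systolic/dicrotic shape, rescaled per beat to
  [DBP, SBP] and raised to a per-beat exponent chosen so the beat's
  time-average equals MAP.

Beat times come from integrating the instantaneous HR of the ground-truth
trajectory (an inhomogeneous point process without RR jitter by default).
All synthesis is vectorized over samples; records of 10^6+ samples build in
well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ..exceptions import InvalidRecordError
from .coupling import CouplingParams, MorphologyCoupling
from .trajectory import HemodynamicTrajectory

_MIN_FS = 100.0
ART_DELAY_S = 0.15   # fixed pressure-wave delay from R peak to arterial upstroke

# ---------------------------------------------------------------- templates

_PPG_A, _PPG_B = 2.0, 5.0
_PPG_MAIN_MAX = (_PPG_A / (_PPG_A + _PPG_B)) ** _PPG_A * (_PPG_B / (_PPG_A + _PPG_B)) ** _PPG_B
_PPG_DICROTIC_MU, _PPG_DICROTIC_SD = 0.55, 0.08


def _ppg_main(phi: np.ndarray) -> np.ndarray:
    return np.where(
        (phi > 0) & (phi < 1),
        phi ** _PPG_A * (1.0 - np.clip(phi, 0, 1)) ** _PPG_B / _PPG_MAIN_MAX,
        0.0,
    )


def _ppg_bump(phi: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((phi - _PPG_DICROTIC_MU) / _PPG_DICROTIC_SD) ** 2)


def _tangent_foot_phase() -> float:
    """Phase offset of the intersecting-tangents foot of the PPG template.

    Tangent at the maximum-slope point of the rising edge, intersected with
    the zero baseline; computed numerically once."""
    phi = np.linspace(1e-6, 0.5, 40001)
    s = _ppg_main(phi)
    ds = np.gradient(s, phi)
    i = int(np.argmax(ds))
    return float(phi[i] - s[i] / ds[i])


_PPG_FOOT_PHASE = _tangent_foot_phase()

_ART_MU1, _ART_SD1 = 0.18, 0.10
_ART_MU2, _ART_SD2, _ART_AMP2 = 0.45, 0.08, 0.35


def _art_shape(phi: np.ndarray) -> np.ndarray:
    h = (np.exp(-0.5 * ((phi - _ART_MU1) / _ART_SD1) ** 2)
         + _ART_AMP2 * np.exp(-0.5 * ((phi - _ART_MU2) / _ART_SD2) ** 2))
    return h


_ART_GRID = np.linspace(0.0, 1.0, 4096, endpoint=False)
_ART_PEAK = float(_art_shape(_ART_GRID).max())
_ART_H = _art_shape(_ART_GRID) / _ART_PEAK
_ART_GAMMAS = np.linspace(0.25, 4.0, 256)
# mean of h^gamma over one beat, monotone decreasing in gamma
_ART_MEANS = np.array([np.mean(_ART_H ** g) for g in _ART_GAMMAS])


def _gamma_for_mean(m_target: np.ndarray) -> np.ndarray:
    """Per-beat exponent so that mean(h^gamma) equals (MAP-DBP)/(SBP-DBP)."""
    # _ART_MEANS is decreasing; np.interp needs ascending x
    return np.interp(m_target, _ART_MEANS[::-1], _ART_GAMMAS[::-1])

# ------------------------------------------------------------------- types


@dataclass
class SubjectTruth:
    """Ground truth carried by synthetic records for oracle testing."""

    trajectory: HemodynamicTrajectory | None
    beat_times: np.ndarray   # s, R-peak times
    rr_s: np.ndarray         # per-beat RR (last beat repeats previous)
    hr_bpm: np.ndarray       # instantaneous 60/RR
    pat_ms: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    ppg_amp: np.ndarray
    ppg_refl: np.ndarray


@dataclass
class SubjectRecord:
    """One subject's synchronized waveforms plus logs and optional truth."""

    subject_id: str
    fs_ecg: float
    fs_ppg: float
    fs_art: float
    ecg: np.ndarray
    ppg: np.ndarray
    art: np.ndarray
    truth: SubjectTruth | None = None
    artifact_log: list = field(default_factory=list)   # (start_s, end_s, kind)
    relevel_log: list = field(default_factory=list)    # (time_s, offset_cm)

    @property
    def duration(self) -> float:
        return len(self.art) / self.fs_art

    def copy(self) -> "SubjectRecord":
        return replace(
            self,
            ecg=self.ecg.copy(), ppg=self.ppg.copy(), art=self.art.copy(),
            artifact_log=list(self.artifact_log),
            relevel_log=list(self.relevel_log),
        )

    def validate(self) -> "SubjectRecord":
        durs = [len(self.ecg) / self.fs_ecg, len(self.ppg) / self.fs_ppg,
                len(self.art) / self.fs_art]
        tol = max(1.0 / self.fs_ecg, 1.0 / self.fs_ppg, 1.0 / self.fs_art)
        if max(durs) - min(durs) > tol + 1e-12:
            raise InvalidRecordError("channel durations differ by more than one sample period")
        if self.truth is not None:
            bt = self.truth.beat_times
            if np.any(np.diff(bt) <= 0):
                raise InvalidRecordError("truth beat times must be strictly increasing")
        for start, end, _kind in self.artifact_log:
            if not (0 <= start < end <= self.duration + tol):
                raise InvalidRecordError("artifact interval outside record duration")
        return self


# --------------------------------------------------------------- synthesis


def beat_times_from_hr(traj: HemodynamicTrajectory) -> np.ndarray:
    """Integrate instantaneous HR into beat (R-peak) times."""
    phase = cumulative_trapezoid(traj.hr / 60.0, traj.time, initial=0.0)
    ks = np.arange(0.5, phase[-1] - 0.5, 1.0)
    return np.interp(ks, phase, traj.time)


def synthesize_waveforms(
    traj: HemodynamicTrajectory,
    coupling: CouplingParams,
    fs: float,
    seed: int,
    *,
    morphology: MorphologyCoupling | None = None,
    ecg_noise_sd: float = 0.01,
    ppg_noise_sd: float = 0.004,
    art_noise_sd: float = 0.0,
) -> SubjectRecord:
    """Render a subject's three synchronized waveforms from ground truth.

    All three channels share the sampling rate ``fs`` (>= 100 Hz).  Truth
    beat-level PAT follows the subject's coupling law (BP inversion + HR
    confound + noise); PPG amplitude/reflection follow ``morphology``.
    Identical inputs give bit-identical records.
    """
    if fs < _MIN_FS:
        raise InvalidRecordError(f"fs must be >= {_MIN_FS} Hz (fiducials unresolvable below)")
    traj.validate()
    morphology = morphology or MorphologyCoupling()
    rng = np.random.default_rng(seed)

    bt = beat_times_from_hr(traj)
    if len(bt) < 3:
        raise InvalidRecordError("trajectory too short to place beats")
    rr = np.empty_like(bt)
    rr[:-1] = np.diff(bt)
    rr[-1] = rr[-2]
    hr_inst = 60.0 / rr
    state = traj.interp(bt)
    sbp_b, dbp_b, map_b = state["sbp"], state["dbp"], state["map"]

    pat = coupling.pat_ms(map_b, hr_inst, rng if coupling.noise_sd_pat > 0 else None)
    pat = np.clip(pat, 110.0, 0.55 * rr * 1000.0)
    amp = morphology.amplitudes(map_b, rng)
    refl = morphology.reflections(map_b, rng)

    duration = traj.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # --- ECG: localized QRS templates around each beat time
    ecg = np.zeros(n)
    idx = np.searchsorted(bt, t)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(bt) - 1)
        dt = t - bt[j]
        ecg += (np.exp(-0.5 * (dt / 0.012) ** 2)
                - 0.16 * np.exp(-0.5 * ((dt + 0.038) / 0.009) ** 2)
                - 0.22 * np.exp(-0.5 * ((dt - 0.038) / 0.009) ** 2))
    # the two nearest-beat passes can both pick beat j for mid-RR samples;
    # templates there are ~exp(-350) so double counting is numerically nil
    if ecg_noise_sd > 0:
        ecg += rng.normal(0.0, ecg_noise_sd, n)

    # --- PPG: one pulse per beat, tangent-foot pinned at r + PAT
    foot = bt + pat / 1000.0
    onset = foot - _PPG_FOOT_PHASE * rr
    j = np.searchsorted(onset, t, side="right") - 1
    jc = np.clip(j, 0, len(bt) - 1)
    phi = (t - onset[jc]) / rr[jc]
    inside = (j >= 0) & (phi >= 0.0) & (phi < 1.0)
    ppg = np.where(
        inside,
        amp[jc] * (_ppg_main(np.clip(phi, 0, 1)) + refl[jc] * _ppg_bump(phi)),
        0.0,
    )
    if ppg_noise_sd > 0:
        ppg += rng.normal(0.0, ppg_noise_sd, n)

    # --- Arterial: contiguous per-beat pulses scaled to [DBP, SBP], mean MAP
    m_target = np.clip((map_b - dbp_b) / (sbp_b - dbp_b), _ART_MEANS.min(), _ART_MEANS.max())
    gamma = _gamma_for_mean(m_target)
    a_on = bt + ART_DELAY_S
    j = np.searchsorted(a_on, t, side="right") - 1
    jc = np.clip(j, 0, len(bt) - 1)
    phi = np.clip((t - a_on[jc]) / rr[jc], 0.0, 1.0)
    h = _art_shape(phi) / _ART_PEAK
    art = dbp_b[jc] + (sbp_b[jc] - dbp_b[jc]) * np.clip(h, 0.0, 1.0) ** gamma[jc]
    art[j < 0] = dbp_b[0]     # run-in before the first pulse
    if art_noise_sd > 0:
        art += rng.normal(0.0, art_noise_sd, n)

    truth = SubjectTruth(
        trajectory=traj, beat_times=bt, rr_s=rr, hr_bpm=hr_inst, pat_ms=pat,
        sbp=sbp_b, dbp=dbp_b, map=map_b, ppg_amp=amp, ppg_refl=refl,
    )
    rec = SubjectRecord(
        subject_id=coupling.subject_id, fs_ecg=fs, fs_ppg=fs, fs_art=fs,
        ecg=ecg, ppg=ppg, art=art, truth=truth,
    )
    return rec.validate()
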
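"""Per-subject haemodynamic trajectories (SBP/DBP/MAP/HR on a 1-s grid).

Trajectories are the ground truth that waveform synthesis, processing and
model evaluation are checked against.  Each registered scenario is a
deterministic function of its seed and composes three ingredients:

* a smooth baseline wander (Gaussian noise low-passed with a correlation
  time, so the series is differentiable at the beat scale),
* raised-cosine "episodes" (hypotension with reflex tachycardia,
  hypertensive surges, isometric-exercise bouts), and
* per-sample event labels so downstream analyses can locate episodes
  without re-detecting them.

MAP defaults to the standard one-third pulse-pressure approximation
MAP = DBP + (SBP - DBP)/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..exceptions import InvalidRecordError, UnknownScenarioError

LABEL_STABLE = "stable"
LABEL_HYPO_TACHY = "hypotension_tachycardia"
LABEL_HYPERTENSION = "hypertension"
LABEL_RECAL = "recalibration_boundary"

_MIN_DURATION_S = 600.0
_GRID_DT_S = 1.0


@dataclass
class HemodynamicTrajectory:
    """Ground-truth BP/HR time series on a uniform grid (step <= 1 s)."""

    time: np.ndarray          # s
    sbp: np.ndarray           # mmHg
    dbp: np.ndarray           # mmHg
    map: np.ndarray           # mmHg
    hr: np.ndarray            # beats/min
    event_labels: np.ndarray  # categorical, one per sample
    scenario: str = "custom"

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0] + _GRID_DT_S)

    def validate(self) -> "HemodynamicTrajectory":
        t = np.asarray(self.time, float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise InvalidRecordError("time grid must be strictly increasing")
        if np.max(np.diff(t)) > 1.0 + 1e-9:
            raise InvalidRecordError("time grid step must be <= 1 s")
        if not (np.all(self.dbp < self.map) and np.all(self.map < self.sbp)):
            raise InvalidRecordError("require dbp < map < sbp at every sample")
        if np.any(self.dbp < 30) or np.any(self.sbp > 250):
            raise InvalidRecordError("BP outside [30, 250] mmHg support")
        if np.any(self.hr < 20) or np.any(self.hr > 220):
            raise InvalidRecordError("HR outside [20, 220] bpm support")
        pp = self.sbp - self.dbp
        lo = self.dbp + pp / 4.0
        hi = self.dbp + pp / 2.0
        if np.any(self.map < lo - 1e-9) or np.any(self.map > hi + 1e-9):
            raise InvalidRecordError("MAP outside [dbp + pp/4, dbp + pp/2]")
        return self

    def interp(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """Linear interpolation of the state at arbitrary times."""
        times = np.asarray(times, float)
        return {
            name: np.interp(times, self.time, getattr(self, name))
            for name in ("sbp", "dbp", "map", "hr")
        }


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, corr_s: float) -> np.ndarray:
    """Zero-mean noise with marginal SD `sd` and correlation time ~`corr_s`."""
    if sd <= 0:
        return np.zeros(n)
    w = gaussian_filter1d(rng.standard_normal(n + 64), corr_s, mode="reflect")[32:-32]
    s = w.std()
    return sd * (w - w.mean()) / (s if s > 0 else 1.0)


def _bump(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Raised-cosine window: 0 outside [t0, t1], 1 at the centre."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    w[inside] = np.sin(np.pi * (t[inside] - t0) / (t1 - t0)) ** 2
    return w


def _finalize(t, sbp, dbp, hr, labels, scenario, dbp_map_frac=1.0 / 3.0):
    sbp = np.clip(sbp, 75.0, 245.0)
    dbp = np.clip(dbp, 35.0, 200.0)
    dbp = np.minimum(dbp, sbp - 15.0)   # keep pulse pressure physiological
    hr = np.clip(hr, 35.0, 190.0)
    mapv = dbp + (sbp - dbp) * dbp_map_frac
    traj = HemodynamicTrajectory(
        time=t, sbp=sbp, dbp=dbp, map=mapv, hr=hr,
        event_labels=labels, scenario=scenario,
    )
    return traj.validate()


def _scenario_stable(t, rng, sbp0, dbp0, hr0):
    sbp = sbp0 + _smooth_noise(rng, len(t), 1.5, 60)
    dbp = dbp0 + _smooth_noise(rng, len(t), 1.0, 60)
    hr = hr0 + _smooth_noise(rng, len(t), 2.0, 60)
    labels = np.full(len(t), LABEL_STABLE, dtype=object)
    return sbp, dbp, hr, labels


def _scenario_hypotension_tachycardia(t, rng, sbp0, dbp0, hr0):
    dur = t[-1] - t[0] + _GRID_DT_S
    sbp, dbp, hr, labels = _scenario_stable(t, rng, sbp0, dbp0, hr0)
    n_ep = max(1, int(round(dur / 3600.0)))
    for j in range(n_ep):
        seg0 = t[0] + j * dur / n_ep
        width = min(600.0, 0.4 * dur / n_ep)
        c = seg0 + 0.6 * dur / n_ep
        w = _bump(t, c - width / 2, c + width / 2)
        sbp -= 30.0 * w
        dbp -= 12.0 * w
        hr += 25.0 * w
        labels[w > 0.2] = LABEL_HYPO_TACHY
    return sbp, dbp, hr, labels


def _scenario_hypertension(t, rng, sbp0, dbp0, hr0):
    dur = t[-1] - t[0] + _GRID_DT_S
    sbp, dbp, hr, labels = _scenario_stable(t, rng, sbp0, dbp0, hr0)
    n_ep = max(1, int(round(dur / 3600.0)))
    for j in range(n_ep):
        seg0 = t[0] + j * dur / n_ep
        width = min(700.0, 0.4 * dur / n_ep)
        c = seg0 + 0.5 * dur / n_ep
        w = _bump(t, c - width / 2, c + width / 2)
        sbp += 30.0 * w
        dbp += 12.0 * w
        hr -= 5.0 * w
        labels[w > 0.2] = LABEL_HYPERTENSION
    return sbp, dbp, hr, labels


def _scenario_mixed_icu(t, rng, sbp0, dbp0, hr0):
    """ICU-like record: drift + a hypertensive surge in the first half and a
    hypotension-with-tachycardia episode in the second half.

    The SBP deviation is rescaled so the realized within-subject SBP range
    falls in the band reported for real ICU cohorts (roughly 25-42 mmHg)."""
    dur = t[-1] - t[0] + _GRID_DT_S
    n = len(t)
    target_range = rng.uniform(27.0, 40.0)
    drift = _smooth_noise(rng, n, 2.5, 450)
    w_hyper = _bump(t, t[0] + 0.12 * dur, t[0] + 0.40 * dur)
    w_hypo = _bump(t, t[0] + 0.58 * dur, t[0] + 0.84 * dur)
    dev = drift + 15.0 * w_hyper - 20.0 * w_hypo
    scale = target_range / (dev.max() - dev.min())
    sbp = sbp0 + scale * dev + _smooth_noise(rng, n, 0.7, 25)
    dbp = dbp0 + 0.5 * scale * dev + _smooth_noise(rng, n, 0.6, 40)
    hr = (hr0 + _smooth_noise(rng, n, 4.0, 300) + 26.0 * w_hypo
          - 4.0 * w_hyper + _smooth_noise(rng, n, 1.0, 20))
    labels = np.full(n, LABEL_STABLE, dtype=object)
    labels[w_hyper > 0.2] = LABEL_HYPERTENSION
    labels[w_hypo > 0.2] = LABEL_HYPO_TACHY
    return sbp, dbp, hr, labels


def _scenario_isometric_exercise(t, rng, sbp0, dbp0, hr0):
    """Repeated isometric-exercise bouts: BP and HR rise together.

    Used to build the general-population training cohort for the
    population-level PAT model, deliberately distinct from the ICU
    evaluation scenario."""
    n = len(t)
    sbp = sbp0 + _smooth_noise(rng, n, 2.0, 60)
    dbp = dbp0 + _smooth_noise(rng, n, 1.2, 60)
    hr = hr0 + _smooth_noise(rng, n, 3.0, 120)
    labels = np.full(n, LABEL_STABLE, dtype=object)
    period = 300.0
    bout = 0.0
    while bout + period <= t[-1] - t[0] + _GRID_DT_S:
        amp = 1.0 + 0.25 * rng.standard_normal()
        w = _bump(t, t[0] + bout + 30.0, t[0] + bout + 210.0)
        sbp += 28.0 * amp * w
        dbp += 11.0 * amp * w
        hr += 22.0 * max(amp, 0.3) * w
        bout += period
    return sbp, dbp, hr, labels


SCENARIOS = {
    "stable": _scenario_stable,
    "hypotension_tachycardia": _scenario_hypotension_tachycardia,
    "hypertension": _scenario_hypertension,
    "mixed_icu": _scenario_mixed_icu,
    "isometric_exercise": _scenario_isometric_exercise,
}


def generate_trajectory(
    scenario: str,
    duration_s: float,
    seed: int,
    *,
    sbp0: float = 130.0,
    dbp0: float = 62.0,
    hr0: float = 78.0,
) -> HemodynamicTrajectory:
    """Generate one subject's ground-truth haemodynamic trajectory.

    Parameters
    ----------
    scenario
        One of ``SCENARIOS`` (``stable``, ``hypotension_tachycardia``,
        ``hypertension``, ``mixed_icu``, ``isometric_exercise``).
    duration_s
        Record length in seconds, at least 600.
    seed
        Any value accepted by :func:`numpy.random.default_rng`; identical
        (scenario, duration, seed, baselines) give bit-identical output.
    sbp0, dbp0, hr0
        Subject resting baselines; cohort generators draw these per subject.
    """
    if scenario not in SCENARIOS:
        raise UnknownScenarioError(
            f"unknown scenario {scenario!r}; registered scenarios: "
            f"{sorted(SCENARIOS)}"
        )
    if duration_s < _MIN_DURATION_S:
        raise InvalidRecordError(f"duration must be >= {_MIN_DURATION_S} s")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, float(duration_s), _GRID_DT_S)
    sbp, dbp, hr, labels = SCENARIOS[scenario](t, rng, sbp0, dbp0, hr0)
    return _finalize(t, sbp, dbp, hr, labels, scenario)
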
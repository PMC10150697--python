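"""Artifact injection and transducer-relevelling offsets for synthetic records.

Artifact kinds mirror what corrupts real arterial-line recordings: flush /
blood-sampling square waves, catheter detachment flatlines, broadband noise
bursts (which also hit the wearable's ECG/PPG), and same-arm cuff inflations
that squeeze the pulse pressure.  Every injected interval is logged so tests
can diff against the clean record; samples outside logged intervals are
bit-identical to the input.
"""

from __future__ import annotations

import numpy as np

from ..bp_models.calibration import hydrostatic_bias
from ..exceptions import InvalidRecordError
from .trajectory import LABEL_RECAL
from .waveforms import SubjectRecord

ARTIFACT_KINDS = (
    "flush_square_wave",
    "flatline_detachment",
    "noise_burst",
    "cuff_inflation_ramp",
)

_DURATION_S = {
    "flush_square_wave": (6.0, 14.0),
    "flatline_detachment": (10.0, 40.0),
    "noise_burst": (5.0, 20.0),
    "cuff_inflation_ramp": (30.0, 60.0),
}


def _apply_flush(rec: SubjectRecord, i0: int, i1: int, rng) -> None:
    t = np.arange(i1 - i0) / rec.fs_art
    plateau = 265.0 + 12.0 * np.sin(2 * np.pi * 4.0 * t)
    edge = np.minimum(1.0, t / 0.5) * np.minimum(1.0, (t[-1] - t) / 0.5 if len(t) > 1 else 1.0)
    rec.art[i0:i1] = rec.art[i0:i1] * (1 - edge) + plateau * edge


def _apply_flatline(rec: SubjectRecord, i0: int, i1: int, rng) -> None:
    hold = rec.art[max(i0 - 1, 0)]
    rec.art[i0:i1] = hold + rng.normal(0.0, 0.3, i1 - i0)


def _apply_noise_burst(rec: SubjectRecord, i0: int, i1: int, rng) -> None:
    n = i1 - i0
    rec.ecg[i0:i1] += rng.normal(0.0, 0.6, n)
    rec.ppg[i0:i1] += rng.normal(0.0, 0.35, n)
    rec.art[i0:i1] += rng.normal(0.0, 18.0, n)


def _apply_cuff(rec: SubjectRecord, i0: int, i1: int, rng) -> None:
    n = i1 - i0
    seg = rec.art[i0:i1]
    local_mean = seg.mean()
    ramp = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
    # cuff on the same arm damps pulsatility and superimposes inflation pressure
    rec.art[i0:i1] = (seg * (1 - 0.95 * ramp)
                      + (local_mean + 60.0 * ramp) * (0.95 * ramp))


_APPLY = {
    "flush_square_wave": _apply_flush,
    "flatline_detachment": _apply_flatline,
    "noise_burst": _apply_noise_burst,
    "cuff_inflation_ramp": _apply_cuff,
}


def inject_artifacts(
    rec: SubjectRecord,
    rate_per_hour: float,
    seed: int,
    *,
    kinds: tuple[str, ...] = ARTIFACT_KINDS,
) -> SubjectRecord:
    """Return a copy of ``rec`` with Poisson-scheduled artifacts injected.

    ``rate_per_hour`` is the expected number of events per hour; events that
    would overlap an earlier one are dropped.  ``rate_per_hour == 0`` returns
    an identical copy with an unchanged log.
    """
    if rate_per_hour < 0:
        raise InvalidRecordError("artifact rate must be >= 0")
    for k in kinds:
        if k not in _APPLY:
            raise InvalidRecordError(f"unknown artifact kind {k!r}")
    out = rec.copy()
    if rate_per_hour == 0:
        return out
    rng = np.random.default_rng(seed)
    duration = rec.duration
    n_events = rng.poisson(rate_per_hour * duration / 3600.0)
    starts = np.sort(rng.uniform(0.0, duration, n_events))
    taken: list[tuple[float, float]] = []
    for s in starts:
        kind = kinds[rng.integers(len(kinds))]
        lo, hi = _DURATION_S[kind]
        e = min(s + rng.uniform(lo, hi), duration)
        if e - s < 2.0 or any(s < te and e > ts for ts, te in taken):
            continue
        i0, i1 = int(round(s * rec.fs_art)), int(round(e * rec.fs_art))
        if i1 <= i0:
            continue
        _APPLY[kind](out, i0, i1, rng)
        out.artifact_log.append((float(s), float(e), kind))
        taken.append((s, e))
    return out.validate()


def apply_relevel_offset(rec: SubjectRecord, at_s: float, offset_cm: float) -> SubjectRecord:
    """Shift the arterial channel from ``at_s`` on by the hydrostatic bias of
    a transducer height offset of ``offset_cm`` (relative to the phlebostatic
    axis).  ECG/PPG are untouched; the event is appended to ``relevel_log``
    and, when truth is present, labelled as a recalibration boundary."""
    if not (0.0 < at_s < rec.duration):
        raise InvalidRecordError(f"relevel time {at_s} outside record (0, {rec.duration})")
    out = rec.copy()
    i0 = int(round(at_s * rec.fs_art))
    out.art[i0:] += hydrostatic_bias(offset_cm)
    out.relevel_log.append((float(at_s), float(offset_cm)))
    if out.truth is not None:
        from dataclasses import replace as _replace
        traj = out.truth.trajectory
        labels = traj.event_labels.copy()
        k = int(np.searchsorted(traj.time, at_s))
        if 0 <= k < len(labels):
            labels[k] = LABEL_RECAL
        out.truth = _replace(out.truth, trajectory=_replace(traj, event_labels=labels))
    return out
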
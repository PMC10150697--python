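"""Static calibration (offset correction) and the hydrostatic-bias helper.

Cuffless estimates are aligned to the invasive reference by a constant
offset computed over a 3-minute window of paired epochs — once at the start
of the test period and again whenever the pressure transducer is relevelled.
The offset history is kept so each prediction uses exactly the offset active
at its own time (never a future one).
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field

import numpy as np

from ..exceptions import CalibrationWindowError

_RHO_KG_M3 = 1000.0      # saline-filled transducer tubing
_G_M_S2 = 9.80665
_PA_PER_MMHG = 133.322

DEFAULT_CAL_WINDOW_S = 180.0


def hydrostatic_bias(offset_cm: float) -> float:
    """Pressure bias (mmHg) of a transducer height offset (cm).

    rho * g * h converted to mmHg; sign follows the sign of the offset.
    A 5 cm offset gives 3.7 mmHg (to one decimal).
    """
    return _RHO_KG_M3 * _G_M_S2 * (float(offset_cm) / 100.0) / _PA_PER_MMHG


@dataclass
class CalibrationState:
    """Time-sorted history of static offsets; one offset active at any t."""

    window_s: float = DEFAULT_CAL_WINDOW_S
    offsets: list = field(default_factory=list)   # (effective_from_s, offset_mmHg)

    def add(self, effective_from: float, offset: float) -> "CalibrationState":
        self.offsets = [(t, o) for t, o in self.offsets if t != effective_from]
        insort(self.offsets, (float(effective_from), float(offset)))
        return self

    def offset_at(self, times) -> np.ndarray:
        """Active offset for each time (0 before the first calibration)."""
        times = np.atleast_1d(np.asarray(times, float))
        if not self.offsets:
            return np.zeros_like(times)
        knots = np.array([t for t, _ in self.offsets])
        vals = np.array([o for _, o in self.offsets])
        idx = np.searchsorted(knots, times, side="right") - 1
        out = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)
        return out

    def apply(self, estimates, times) -> np.ndarray:
        return np.asarray(estimates, float) + self.offset_at(times)


def calibrate(
    predictions,
    reference,
    epoch_start,
    at: float,
    *,
    window_s: float = DEFAULT_CAL_WINDOW_S,
    state: CalibrationState | None = None,
) -> CalibrationState:
    """Compute a static offset over [at, at + window_s) and record it.

    The offset is mean(reference) - mean(prediction) over the paired epochs
    in the window, so the post-calibration mean error over that window is
    zero by construction.  Raises if the paired series does not cover the
    window (fewer than ~3 minutes of epochs available from ``at``).
    """
    predictions = np.asarray(predictions, float)
    reference = np.asarray(reference, float)
    epoch_start = np.asarray(epoch_start, float)
    if not (len(predictions) == len(reference) == len(epoch_start)):
        raise CalibrationWindowError("predictions/reference/epoch_start lengths differ")
    in_win = (epoch_start >= at) & (epoch_start < at + window_s)
    n_win = int(in_win.sum())
    if n_win == 0 or epoch_start.max() < at + window_s * 0.9:
        raise CalibrationWindowError(
            f"need >= {window_s} s of paired epochs from t={at}; "
            f"window holds {n_win} epochs, series ends at {epoch_start.max() if len(epoch_start) else 'n/a'}"
        )
    step = float(np.median(np.diff(np.unique(epoch_start)))) if len(epoch_start) > 1 else window_s
    if n_win * step < 0.6 * window_s:
        raise CalibrationWindowError(
            f"only {n_win} epochs (~{n_win * step:.0f} s) inside the {window_s} s window"
        )
    offset = float(reference[in_win].mean() - predictions[in_win].mean())
    state = state if state is not None else CalibrationState(window_s=window_s)
    state.add(at, offset)
    return state
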
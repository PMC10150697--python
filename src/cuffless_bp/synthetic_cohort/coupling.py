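"""Subject-level PAT-BP-HR coupling and PPG morphology coupling.

The simulator's causal story, per subject:

    BP = beta0 + beta_pat * PAT_bp + beta_hr * HR (+ beta_inter * PAT_bp * HR)

defines the BP-related component of pulse arrival time by inversion, and the
*observed* PAT adds an HR confound (sympathetically driven pre-ejection-period
shortening: a rise in HR shortens PAT regardless of BP) plus measurement
noise:

    PAT_obs = PAT_bp + hr_confound * (HR - hr_ref) + eps,   eps ~ N(0, noise_sd_pat)

``beta_pat`` is negative (shorter PAT <-> higher BP) and ``hr_confound`` is
non-positive.  The BP component driving the inversion is MAP.

PPG pulse morphology (relative amplitude and the dicrotic/reflection ratio)
is coupled to MAP with subject-specific gains; these are the "extra" sensor
features a subject-specific model can exploit beyond PAT and HR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..exceptions import InvalidRecordError

HR_REF_BPM = 70.0  # anchor for the HR confound term


@dataclass(frozen=True)
class CouplingParams:
    """Per-subject PAT-BP-HR coupling coefficients.

    Units: beta0 mmHg; beta_pat mmHg/ms (< 0); beta_hr mmHg/bpm;
    beta_inter mmHg/(ms*bpm); hr_confound ms/bpm (<= 0); noise_sd_pat ms.
    """

    subject_id: str
    beta0: float
    beta_pat: float
    beta_hr: float = 0.0
    beta_inter: float = 0.0
    hr_confound: float = 0.0
    noise_sd_pat: float = 0.0

    def __post_init__(self):
        if not self.beta_pat < 0:
            raise InvalidRecordError("beta_pat must be negative (shorter PAT <-> higher BP)")
        if self.hr_confound > 0:
            raise InvalidRecordError("hr_confound must be <= 0 (HR rise shortens PAT)")
        if self.noise_sd_pat < 0:
            raise InvalidRecordError("noise_sd_pat must be >= 0")

    def with_(self, **kw) -> "CouplingParams":
        return replace(self, **kw)

    def pat_bp_ms(self, map_mmhg: np.ndarray, hr_bpm: np.ndarray) -> np.ndarray:
        """BP-related PAT component: inversion of the linear BP law."""
        slope = self.beta_pat + self.beta_inter * np.asarray(hr_bpm, float)
        if np.any(slope >= 0):
            raise InvalidRecordError("beta_pat + beta_inter*HR must stay negative")
        return (np.asarray(map_mmhg, float) - self.beta0 - self.beta_hr * hr_bpm) / slope

    def pat_ms(self, map_mmhg, hr_bpm, rng: np.random.Generator | None = None) -> np.ndarray:
        """Observed PAT: BP component + HR confound + optional noise."""
        hr_bpm = np.asarray(hr_bpm, float)
        pat = self.pat_bp_ms(map_mmhg, hr_bpm) + self.hr_confound * (hr_bpm - HR_REF_BPM)
        if self.noise_sd_pat > 0:
            if rng is None:
                raise InvalidRecordError("rng required when noise_sd_pat > 0")
            pat = pat + rng.normal(0.0, self.noise_sd_pat, size=np.shape(pat))
        return pat


@dataclass(frozen=True)
class MorphologyCoupling:
    """PPG pulse-shape coupling to MAP (subject-specific gains).

    amplitude = amp0 * (1 + amp_map_gain * (MAP - map_anchor)) * (1 + rel. noise)
    reflection = clip(refl0 + refl_map_gain * (MAP - map_anchor) + noise, 0.05, 0.45)
    """

    amp0: float = 1.0
    amp_map_gain: float = -0.010      # per mmHg
    amp_noise_rel: float = 0.06
    refl0: float = 0.20
    refl_map_gain: float = 0.004      # per mmHg
    refl_noise_sd: float = 0.02
    map_anchor: float = 85.0

    def amplitudes(self, map_mmhg, rng: np.random.Generator) -> np.ndarray:
        m = np.asarray(map_mmhg, float)
        a = self.amp0 * (1.0 + self.amp_map_gain * (m - self.map_anchor))
        if self.amp_noise_rel > 0:
            a = a * (1.0 + rng.normal(0.0, self.amp_noise_rel, size=m.shape))
        return np.clip(a, 0.1 * self.amp0, None)

    def reflections(self, map_mmhg, rng: np.random.Generator) -> np.ndarray:
        m = np.asarray(map_mmhg, float)
        r = self.refl0 + self.refl_map_gain * (m - self.map_anchor)
        if self.refl_noise_sd > 0:
            r = r + rng.normal(0.0, self.refl_noise_sd, size=m.shape)
        return np.clip(r, 0.05, 0.45)


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_coupling(
    subject_id: str,
    rng: np.random.Generator,
    *,
    population: str = "icu",
    map_anchor: float = 85.0,
    hr_anchor: float = HR_REF_BPM,
    pat_anchor_ms: tuple[float, float] = (235.0, 22.0),
    noise_sd_pat: float | None = None,
    heterogeneity: float = 1.0,
) -> CouplingParams:
    """Draw one subject's coupling from a population distribution.

    Two populations are built in.  ``"general"`` is the healthy cohort the
    population-level PAT model is trained on (mild HR confound).  ``"icu"``
    draws a markedly stronger HR confound (consistent with elevated
    sympathetic tone in critical illness), which is what breaks a
    population-trained PAT model during hypotension-with-tachycardia.
    The distributions are plausible placeholders: no published quantitative
    distribution of these coefficients exists for either cohort.
    ``heterogeneity`` scales every between-subject SD (0 gives an idealized
    cohort sharing one coupling law, useful for exact-recovery oracles).
    """
    het = float(heterogeneity)
    if population == "general":
        beta_pat = _truncnorm(rng, -0.70, 0.12 * het, hi=-0.35)
        beta_hr = _truncnorm(rng, 0.10, 0.05 * het)
        confound = _truncnorm(rng, -0.40, 0.15 * het, lo=-1.2, hi=0.0)
        noise = 5.0 if noise_sd_pat is None else noise_sd_pat
    elif population == "icu":
        beta_pat = _truncnorm(rng, -0.70, 0.18 * het, hi=-0.35)
        beta_hr = _truncnorm(rng, 0.10, 0.05 * het)
        confound = _truncnorm(rng, -1.20, 0.35 * het, lo=-2.2, hi=-0.5)
        noise = 6.0 if noise_sd_pat is None else noise_sd_pat
    else:
        raise InvalidRecordError(f"unknown coupling population {population!r}")
    pat0 = rng.normal(pat_anchor_ms[0], pat_anchor_ms[1] * het)
    # anchor: at (map_anchor, hr_anchor) the BP-related PAT equals pat0
    beta0 = map_anchor - beta_pat * pat0 - beta_hr * hr_anchor
    return CouplingParams(
        subject_id=subject_id,
        beta0=beta0,
        beta_pat=beta_pat,
        beta_hr=beta_hr,
        beta_inter=0.0,
        hr_confound=confound,
        noise_sd_pat=noise,
    )


def sample_morphology(rng: np.random.Generator) -> MorphologyCoupling:
    """Draw subject-specific PPG morphology gains."""
    return MorphologyCoupling(
        amp0=rng.uniform(0.8, 1.2),
        amp_map_gain=_truncnorm(rng, -0.010, 0.003, hi=-0.004),
        refl0=rng.uniform(0.15, 0.25),
        refl_map_gain=_truncnorm(rng, 0.004, 0.001, lo=0.001),
    )
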
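"""Cohort-level generation: seeded virtual subjects, streamed one at a time.

Per-subject randomness is drawn from streams derived as
``default_rng([master_seed, subject_index, stage])`` so cohort membership is
order-independent: subject k is identical whether generated alone or as part
of a cohort.

Besides the full waveform path there is an epoch-level fast path
(:func:`epoch_table_from_trajectory`) that applies the same coupling laws
directly on the epoch grid; it is used where beat-level waveform rendering
adds nothing (e.g. Monte-Carlo studies of the model fits and statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ..exceptions import ConfigError
from .artifacts import apply_relevel_offset, inject_artifacts
from .coupling import CouplingParams, MorphologyCoupling, sample_coupling, sample_morphology
from .trajectory import HemodynamicTrajectory, generate_trajectory
from .waveforms import SubjectRecord, synthesize_waveforms


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic ICU cohort.

    The defaults *are* the evaluation conditions: 25 subjects, mixed ICU
    scenario with a hypotension+tachycardia episode in the test half,
    ICU-strength HR confound with between-subject variation, occasional
    arterial artifacts and transducer relevels in the test period.
    """

    scenario: str = "mixed_icu"
    n_subjects: int = 25
    duration_s: float = 5400.0
    fs: float = 250.0
    population: str = "icu"          # coupling population: "icu" | "general"
    artifact_rate_per_h: float = 2.0
    relevel_prob: float = 0.4        # chance of one relevel in the test half
    relevel_offset_cm: tuple = (3.0, 7.0)
    hr_confound_scale: float = 1.0   # 0 disables the HR->PAT confound
    heterogeneity_scale: float = 1.0  # 0 -> all subjects share one coupling law
    noiseless: bool = False          # zero all noise + artifacts (oracle mode)
    ecg_noise_sd: float = 0.01
    ppg_noise_sd: float = 0.004
    art_noise_sd: float = 0.0
    sbp0_mean_sd: tuple = (131.0, 12.0)
    dbp0_mean_sd: tuple = (61.0, 6.0)
    hr0_mean_sd: tuple = (78.0, 9.0)

    def __post_init__(self):
        if self.n_subjects < 1 or self.duration_s < 600 or self.fs < 100:
            raise ConfigError("invalid cohort config (n_subjects/duration/fs)")


def _subject_id(cfg: CohortConfig, idx: int) -> str:
    return f"{cfg.scenario}-{idx:03d}"


def draw_subject_params(cfg: CohortConfig, seed: int, idx: int):
    """Baselines, coupling and morphology for subject ``idx`` (order-independent)."""
    rng = np.random.default_rng([seed, idx, 0])
    sbp0 = float(np.clip(rng.normal(*cfg.sbp0_mean_sd), 95.0, 175.0))
    dbp0 = float(np.clip(rng.normal(*cfg.dbp0_mean_sd), 45.0, min(90.0, sbp0 - 35.0)))
    hr0 = float(np.clip(rng.normal(*cfg.hr0_mean_sd), 55.0, 110.0))
    coupling = sample_coupling(_subject_id(cfg, idx), rng, population=cfg.population,
                               heterogeneity=cfg.heterogeneity_scale)
    coupling = coupling.with_(hr_confound=coupling.hr_confound * cfg.hr_confound_scale)
    morph = sample_morphology(rng)
    if cfg.noiseless:
        coupling = coupling.with_(noise_sd_pat=0.0)
        morph = replace(morph, amp_noise_rel=0.0, refl_noise_sd=0.0)
    return sbp0, dbp0, hr0, coupling, morph


def generate_subject(cfg: CohortConfig, seed: int, idx: int) -> SubjectRecord:
    """Generate one complete subject record (trajectory -> waveforms ->
    artifacts -> relevels), deterministically from (config, seed, idx)."""
    sbp0, dbp0, hr0, coupling, morph = draw_subject_params(cfg, seed, idx)
    traj = generate_trajectory(
        cfg.scenario, cfg.duration_s, [seed, idx, 1],
        sbp0=sbp0, dbp0=dbp0, hr0=hr0,
    )
    noise = dict(ecg_noise_sd=cfg.ecg_noise_sd, ppg_noise_sd=cfg.ppg_noise_sd,
                 art_noise_sd=cfg.art_noise_sd)
    if cfg.noiseless:
        noise = dict(ecg_noise_sd=0.0, ppg_noise_sd=0.0, art_noise_sd=0.0)
    rec = synthesize_waveforms(traj, coupling, cfg.fs, [seed, idx, 2],
                               morphology=morph, **noise)
    if not cfg.noiseless and cfg.artifact_rate_per_h > 0:
        rec = inject_artifacts(rec, cfg.artifact_rate_per_h, [seed, idx, 3])
    if not cfg.noiseless and cfg.relevel_prob > 0:
        rng = np.random.default_rng([seed, idx, 4])
        if rng.random() < cfg.relevel_prob:
            at = rng.uniform(0.60, 0.90) * cfg.duration_s
            lo, hi = cfg.relevel_offset_cm
            offset = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            rec = apply_relevel_offset(rec, at, offset)
    return rec


def generate_cohort(cfg: CohortConfig, seed: int) -> Iterator[SubjectRecord]:
    """Stream the cohort's subject records (records are large; process one
    at a time rather than holding the cohort in memory)."""
    for idx in range(cfg.n_subjects):
        yield generate_subject(cfg, seed, idx)


# ------------------------------------------------------------ fast path


def epoch_table_from_trajectory(
    traj: HemodynamicTrajectory,
    coupling: CouplingParams,
    seed: int,
    *,
    epoch_s: float = 15.0,
    morphology: MorphologyCoupling | None = None,
    pat_noise_sd_ms: float | None = None,
) -> pd.DataFrame:
    """Epoch table straight from the trajectory and coupling laws.

    Produces the same schema as the waveform processing chain (reference BP,
    PAT, HR, morphology features, split) but skips beat-level rendering and
    detection, so the PAT-BP-HR relation holds *exactly* when noise is zero.
    ``pat_noise_sd_ms`` defaults to the coupling's beat-level noise shrunk by
    the number of beats averaged per epoch.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(traj.time[0], traj.time[-1] - epoch_s + 1e-9, epoch_s)
    rows = []
    for t0 in edges:
        sel = (traj.time >= t0) & (traj.time < t0 + epoch_s)
        if not sel.any():
            continue
        rows.append((t0, traj.sbp[sel].mean(), traj.dbp[sel].mean(),
                     traj.map[sel].mean(), traj.hr[sel].mean()))
    df = pd.DataFrame(rows, columns=["epoch_start", "ref_sbp", "ref_dbp", "ref_map", "hr"])
    n_beats = np.maximum((df["hr"] / 60.0 * epoch_s).round(), 1.0)
    pat = coupling.with_(noise_sd_pat=0.0).pat_ms(df["ref_map"].to_numpy(), df["hr"].to_numpy())
    sd = (coupling.noise_sd_pat / np.sqrt(n_beats)
          if pat_noise_sd_ms is None else pat_noise_sd_ms)
    if np.any(np.asarray(sd) > 0):
        pat = pat + rng.normal(0.0, 1.0, len(df)) * sd
    df["pat"] = pat
    if morphology is not None:
        mapv = df["ref_map"].to_numpy()
        df["amplitude"] = morphology.amplitudes(mapv, rng)
        df["reflection_ratio"] = morphology.reflections(mapv, rng)
        # timing/area morphology scale with the pulse itself
        df["rise_time"] = 0.33 * 60.0 / df["hr"] * 1000.0 * 0.33
        df["width_50"] = 0.30 * 60.0 / df["hr"] * 1000.0
        df["pulse_area"] = df["amplitude"] * 60.0 / df["hr"] * 0.25
    df["n_valid_beats"] = n_beats.astype(int)
    df["subject_id"] = coupling.subject_id
    from ..waveform_processing.epochs import assign_split
    df["split"] = assign_split(len(df))
    cols = ["subject_id", "epoch_start", "ref_sbp", "ref_dbp", "ref_map", "pat", "hr"]
    cols += [c for c in df.columns if c not in cols + ["n_valid_beats", "split"]]
    return df[cols + ["n_valid_beats", "split"]]
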
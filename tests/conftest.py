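import numpy as np
import pytest

from cuffless_bp.synthetic_cohort import (
    CouplingParams,
    HemodynamicTrajectory,
    MorphologyCoupling,
    generate_trajectory,
    synthesize_waveforms,
)

FS = 250.0


def constant_trajectory(duration_s=600.0, sbp=120.0, dbp=60.0, mapv=80.0, hr=75.0):
    t = np.arange(0.0, duration_s, 1.0)
    n = len(t)
    return HemodynamicTrajectory(
        time=t,
        sbp=np.full(n, sbp), dbp=np.full(n, dbp), map=np.full(n, mapv),
        hr=np.full(n, hr),
        event_labels=np.full(n, "stable", dtype=object),
        scenario="custom",
    ).validate()


def noiseless_coupling(subject_id="s0", hr_confound=0.0, noise_sd_pat=0.0):
    # anchored so PAT ~ 235 ms at MAP 85 / HR 70
    beta_pat, beta_hr = -0.7, 0.1
    beta0 = 85.0 - beta_pat * 235.0 - beta_hr * 70.0
    return CouplingParams(
        subject_id=subject_id, beta0=beta0, beta_pat=beta_pat, beta_hr=beta_hr,
        hr_confound=hr_confound, noise_sd_pat=noise_sd_pat,
    )


def clean_morphology():
    return MorphologyCoupling(amp_noise_rel=0.0, refl_noise_sd=0.0)


@pytest.fixture(scope="session")
def constant_record():
    """Noiseless record from a constant trajectory (SBP 120 / DBP 60 / MAP 80,
    HR 75)."""
    traj = constant_trajectory()
    return synthesize_waveforms(
        traj, noiseless_coupling(), FS, seed=11,
        morphology=clean_morphology(),
        ecg_noise_sd=0.0, ppg_noise_sd=0.0, art_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def stable_record():
    """Noiseless record from a gently wandering 'stable' trajectory."""
    traj = generate_trajectory("stable", 600.0, seed=21)
    return synthesize_waveforms(
        traj, noiseless_coupling(), FS, seed=22,
        morphology=clean_morphology(),
        ecg_noise_sd=0.0, ppg_noise_sd=0.0, art_noise_sd=0.0,
    )
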
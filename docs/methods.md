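# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `cuffless_bp`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimation problem

Pulse arrival time (PAT) — ECG R peak to PPG pulse foot — shortens when BP
rises, because pulse-wave velocity increases with distending pressure. Two
things break the simple PAT→BP map in practice:

1. **Between-subject heterogeneity.** The coefficients linking PAT, HR and
   BP differ across people, so a model pooled over one cohort transfers
   imperfectly to another.
2. **The HR confound.** The pre-ejection period (a component of PAT)
   shortens under sympathetic activation independently of BP. A rise in HR
   therefore shortens PAT even when BP is *falling* — precisely the
   hypotension-with-tachycardia pattern that matters clinically, where a
   PAT model reads the shortened PAT as a BP *increase*.

The package compares a population-trained linear PAT(+HR) model against
per-subject models that can also use PPG morphology, using a full
agreement-statistics suite at 15-s epoch resolution.

## Synthetic cohort: what it emulates

Real recordings are not available, so a simulator defines the study
conditions, with complete ground truth for oracle testing.

**Trajectories** (1-s grid): smoothed Gaussian baseline wander plus
raised-cosine episodes. Registered scenarios: `stable` (SBP SD ≤ 5 mmHg),
`hypotension_tachycardia` (MAP falls ≥ 15 mmHg while HR rises ≥ 15 bpm),
`hypertension`, `mixed_icu` (a hypertensive surge in the first half, a
hypotension+tachycardia episode in the second half, drift; the SBP
deviation is rescaled so each subject's within-subject SBP range falls in
27–40 mmHg, matching the interquartile range reported for real ICU
cohorts), and `isometric_exercise` (BP and HR rising together — the
population-model training regime). MAP defaults to DBP + (SBP − DBP)/3;
the containers only require MAP to lie in [DBP + PP/4, DBP + PP/2].
Per-subject baselines are drawn around SBP 131 (SD 12), DBP 61 (SD 6),
HR 78 (SD 9) — the distributional anchors of published ICU cohorts.

**Coupling.** Each subject carries a linear law
`MAP = β₀ + β_PAT·PAT_bp + β_HR·HR` (β_PAT < 0); the BP-related PAT
component is its inversion, and observed PAT adds the HR confound
`hr_confound·(HR − 70)` (hr_confound ≤ 0) plus Gaussian beat noise.
Defaults: β_PAT ≈ −0.7 mmHg/ms (SD 0.18 between subjects), β_HR ≈ 0.1
mmHg/bpm, PAT anchor 235 ± 22 ms, beat noise 6 ms. The general-population
cohort draws a mild confound (−0.4 ± 0.15 ms/bpm); the ICU cohort draws a
markedly stronger one (−1.2 ± 0.35 ms/bpm, consistent with elevated
sympathetic tone in critical illness). This two-population design is the
package's own choice and is what realizes the documented failure mode: a
population-trained PAT(+HR) model cannot compensate a confound whose
strength it never saw. No published quantitative distributions exist for
these coefficients; they are plausible placeholders, and every test that
depends on them is a directional (not numeric) claim.

**PPG morphology.** Pulse amplitude and the dicrotic (reflection) ratio
are coupled to MAP with subject-specific gains (amplitude gain −1%/mmHg
± 0.3 between subjects, 6% relative beat noise). These stand in for the
"other signal features" a subject-specific learner can exploit; they are
deliberately informative but noisy, so the individualized model's
advantage is structural (it sees them; the population model does not),
not assumed.

**Waveforms** (default 250 Hz, configurable ≥ 100 Hz; tolerances are
expressed in sample periods so they hold at any rate): ECG is a Gaussian R
wave with Q/S side lobes; PPG is an asymmetric beta-shaped pulse
(fast rise, slow decay) with a Gaussian dicrotic bump, placed so that the
*intersecting-tangents foot* of the continuous template lies exactly at
R-peak time + PAT — making the detector round trip bias-free without
sharing code with the detector; the arterial pulse is a two-Gaussian
systolic/dicrotic shape rescaled per beat to [DBP, SBP] and raised to a
per-beat exponent chosen (by inverting a precomputed mean-vs-exponent
table) so the beat's time-average equals MAP. Beat times integrate the
instantaneous HR (no RR jitter by default). Artifacts: flush square waves,
detachment flatlines (pulse pressure < 5 mmHg), broadband noise bursts on
all channels, cuff-inflation ramps; Poisson-scheduled, non-overlapping,
fully logged. Transducer relevels add ρgh/133.322 mmHg steps
(ρ = 1000 kg/m³, g = 9.80665; 5 cm → 3.7 mmHg).

An epoch-level fast path (`epoch_table_from_trajectory`) applies the same
coupling laws directly on the epoch grid, for Monte-Carlo studies where
beat-level rendering adds nothing.

## Processing chain

* **R peaks**: zero-phase 5–25 Hz band-pass, squared energy, 120 ms
  moving average, block-adaptive threshold (0.35 × per-8-s 99th
  percentile, floored at 10% of the median block level so quiet blocks do
  not fire), 200 ms refractory, final location refined as the raw-signal
  argmax within ±40 ms. A flat signal returns no peaks, not an error.
* **PPG foot**: per beat, the tangent at the maximum-slope point within
  (R, R + 0.6·RR) intersected with the preceding-minimum level; sub-sample
  precision; feet outside the window (or flat windows) invalidate the beat.
* **Beat BP**: per window [Rᵢ, Rᵢ₊₁), reference SBP/DBP/MAP =
  max/min/time-average of the raw arterial waveform.
* **Artifact filter** (automatic rules only): SBP outside (40, 300), DBP
  outside (20, 200), pulse pressure < 10 mmHg, MAP outside (DBP, SBP), or
  an SBP jump > 30 mmHg versus the previous valid beat. The jump anchor
  expires after 5 s: without this, one artifact beat that slips through
  the range rules would invalidate every subsequent beat. The 30 mmHg
  threshold is a package choice (no published value): it catches flush
  transients while passing the generator's steepest physiological changes.
* **Epochs**: 15-s half-open windows anchored at the first valid beat;
  means over valid beats only; epochs with < 5 valid beats dropped; first
  half of surviving epochs (by time) = train, second half = test
  (|n_train − n_test| ≤ 1).
* **Subject QC**: include iff valid-beat ratio ≥ 0.6 AND ≥ 200 epoch
  pairs AND SD of first-half reference SBP ≥ 50% of the whole-record SD.
  The source protocol lists criterion (1) with an ambiguous direction; it
  is implemented as *include iff ratio ≥ 0.6*, the evident intent. The SD
  criterion uses SBP (configurable to MAP); the protocol names only
  "reference BP".

## Models and calibration

* **Generalized model**: OLS of the BP component on (PAT, HR, PAT·HR),
  pooled over the exercise cohort; rank checked on the scaled design
  (constant HR → error). The model records its fitting-cohort id and
  refuses evaluation on the same cohort. A PAT-only variant drops the HR
  terms.
* **Individualized model**: ridge regression (default α = 1, optionally
  chosen by leave-contiguous-chunk-out CV within the train split) on
  standardized {PAT, HR, amplitude, rise_time, width_50, pulse_area,
  reflection_ratio}; one model per subject per BP component; any
  test-split row in the training input raises. The real study's
  individualized models are proprietary; a small deterministic learner
  keeps the comparison reproducible while honouring the idea of
  exploiting additional sensor features.
* **Calibration**: offset = mean(reference) − mean(prediction) over
  [t, t + 180 s) of paired epochs (epoch-level, matching the data the
  models emit); applied to predictions from t until the next offset.
  Re-calibration is triggered exactly at logged relevel events inside the
  test period (the real trigger was clinical judgment; the event log is
  the faithful machine-checkable stand-in). Re-calibrations whose 3-min
  window is not covered by remaining epochs are skipped and logged.

## Agreement statistics

Errors are estimate − reference throughout; sample SDs use n−1. MAE is
reported with the SD of absolute errors (the parenthetical in accuracy
tables) and separately the SD of signed errors. Pooled Bland–Altman uses
bias ± 1.96 SD; the repeated-measures variant decomposes the difference
variance by one-way ANOVA (unbalanced n₀ correction; negative
between-subject estimates clipped to zero) — with homoscedastic,
subject-balanced errors it coincides with the pooled limits, which the
suite asserts. rmcorr is the ANCOVA estimator (subject means removed,
residuals correlated, df = N − k − 1). The aggregated regression fits
per-subject mean reference on per-subject mean estimate; AIC = 2k − 2lnL
and BIC = k·ln n − 2lnL use the full Gaussian likelihood with k = 3
(slope, intercept, variance), so absolute values carry the likelihood
constant and only same-data model comparisons are meaningful. The
Diebold–Mariano test uses squared-error loss by default (absolute
available), Newey–West/Bartlett HAC variance with lag ⌊T^{1/3}⌋, and
two-sided normal p-values; d ≡ 0 returns (0, 1) and a constant nonzero
differential returns p = 0 with a degeneracy flag. ADF runs with constant
only (no trend term — callers analysing trending series should note
this), lag by AIC. Fisher's method is X = −2Σln p ~ χ²(2k); zero
p-values are rejected, callers floor them explicitly (the pipeline uses
1e−300). The "non-parametric test for equality of means" of the protocol
is unspecified; Wilcoxon signed-rank on paired absolute errors is used
(paired design on shared epochs); the "variance comparison test" is a
two-sample F-test. Model-vs-model inputs must share identical
(subject, epoch) keys.

## Default problem sizes and determinism

The default study runs 25 ICU subjects × 5400 s (inside the 1.4–8 h
observation range of real cohorts; 360 epochs per subject, comfortably
above the 200-pair QC floor) at 250 Hz, and a 12-subject × 900 s exercise
cohort — desk-scale sizes chosen so a full seeded study runs in well under
a minute. All randomness flows from one master seed through named
SeedSequence streams (`[seed, stream, stage]`), so cohort membership is
order-independent and a rerun with the same config and seed is
bit-identical (reports contain no timestamps).

## Episode-tracking analysis

For every hypotension+tachycardia episode falling in a subject's test
period, the pipeline records the reference MAP change from the pre-episode
mean (up to 4 min before onset) to the episode trough (±1 epoch) and each
model's predicted change over the same epochs. The "captured fraction"
(predicted change / reference change) is the direction statistic: ≈1 means
the model tracks the fall, ≈0 means it flatlines, < 0 means it predicts a
rise during the fall. Episodes with reference drops < 8 mmHg are excluded
as too shallow to classify.

## What passing tests do and do not show

The simulator realizes a world in which the documented mechanisms (PAT–BP
coupling, HR confound, between-subject heterogeneity, morphology
information) are exactly true and stationary; passing tests show the
pipeline measures such a world correctly and that the model comparison
behaves as the mechanisms dictate. They do not show that real ICU data
have these coupling strengths: absolute error magnitudes here are not
comparable to any real-device figure. Other known gaps: no respiration,
no arrhythmia/RR irregularity (excluded from the emulated protocol), no
motion/posture artifacts on the wearable channels beyond noise bursts, no
monitor-derived 5-s BP values (beat-level extraction only), no damping or
resonance in the arterial line, and morphology features that are cleaner
than any real PPG sensor delivers.
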
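"""Study configuration: every protocol constant in one serializable object.

Defaults mirror the validation protocol this package replicates: 15-s
epochs, 3-minute static calibration at the start of the test period,
first-half/second-half train/test split, and the three subject-exclusion
thresholds (valid-signal ratio 0.6, 200 pairs, 50% first-half SD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..exceptions import ConfigError
from ..synthetic_cohort.cohort import CohortConfig


def _default_icu() -> CohortConfig:
    return CohortConfig()


def _default_exercise() -> CohortConfig:
    return CohortConfig(
        scenario="isometric_exercise",
        n_subjects=12,
        duration_s=900.0,
        population="general",
        artifact_rate_per_h=0.0,
        relevel_prob=0.0,
    )


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortConfig = field(default_factory=_default_icu)
    exercise_cohort: CohortConfig = field(default_factory=_default_exercise)
    epoch_s: float = 15.0
    min_beats_per_epoch: int = 5
    cal_window_s: float = 180.0
    qc_min_valid_ratio: float = 0.6
    qc_min_pairs: int = 200
    qc_min_sd_ratio: float = 0.5
    ridge_alpha: float | str = 1.0
    dm_loss: str = "squared"
    significance_alpha: float = 0.05
    targets: tuple = ("sbp", "dbp", "map")

    def __post_init__(self):
        if self.epoch_s <= 0 or self.cal_window_s <= 0:
            raise ConfigError("epoch_s and cal_window_s must be positive")
        if not (0 < self.qc_min_valid_ratio <= 1) or self.qc_min_pairs < 1 \
                or not (0 < self.qc_min_sd_ratio <= 1):
            raise ConfigError("QC thresholds must be positive (ratio in (0,1])")
        for t in self.targets:
            if t not in ("sbp", "dbp", "map"):
                raise ConfigError(f"unknown target {t!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(self.targets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("cohort", "exercise_cohort"):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tkey in ("relevel_offset_cm", "sbp0_mean_sd", "dbp0_mean_sd", "hr0_mean_sd"):
                    if tkey in sub and isinstance(sub[tkey], list):
                        sub[tkey] = tuple(sub[tkey])
                try:
                    d[key] = CohortConfig(**sub)
                except TypeError as exc:
                    raise ConfigError(f"bad {key} section: {exc}") from exc
        if "targets" in d:
            d["targets"] = tuple(d["targets"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad study config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
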
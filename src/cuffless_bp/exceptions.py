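"""Exception types shared across the package."""


class CufflessBPError(Exception):
    """Base class for all package-specific errors."""


class UnknownScenarioError(CufflessBPError, ValueError):
    """Requested a hemodynamic scenario that is not registered."""


class InvalidRecordError(CufflessBPError, ValueError):
    """A SubjectRecord or trajectory violates its invariants or preconditions."""


class RankDeficientDesignError(CufflessBPError, ValueError):
    """Regression design matrix is rank deficient (coefficients unidentifiable)."""


class CalibrationWindowError(CufflessBPError, ValueError):
    """Not enough paired data to cover the static calibration window."""


class SplitLeakageError(CufflessBPError, ValueError):
    """Attempted to train a subject-specific model on test-split epochs."""


class InsufficientDataError(CufflessBPError, ValueError):
    """Too few observations/subjects for the requested statistic or fit."""


class ConfigError(CufflessBPError, ValueError):
    """Invalid study configuration."""


class EmptyCohortError(CufflessBPError, RuntimeError):
    """No subject survived quality control; carries the QC ledger."""

    def __init__(self, message: str, ledger=None):
        super().__init__(message)
        self.ledger = ledger or []
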
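"""cuffless_bp: cuffless blood-pressure estimation and validation.

Pulse-arrival-time (PAT) based and subject-specific BP models with static
calibration, evaluated against invasive arterial reference with a full
agreement-statistics suite, plus a seeded synthetic ICU cohort simulator
providing ground truth for oracle testing.
"""

__version__ = "0.1.0"

from . import agreement_stats, bp_models, synthetic_cohort, waveform_processing  # noqa: E402,F401

__all__ = [
    "agreement_stats", "bp_models", "pipeline", "synthetic_cohort",
    "waveform_processing", "__version__",
]


def __getattr__(name):
    # pipeline imports the subpackages above; lazy access avoids a cycle
    if name == "pipeline":
        from . import pipeline
        return pipeline
    raise AttributeError(name)
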
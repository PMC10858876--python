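"""Exception hierarchy.

Every error raised on bad user input derives from :class:`PeriSeizureError`
(itself a ``ValueError``) so callers can catch the whole family, while the
pipeline distinguishes per-session data problems (quarantined) from
configuration problems (fatal).
"""


class PeriSeizureError(ValueError):
    """Base class for all input/contract violations in this package."""


class ConfigError(PeriSeizureError):
    """Invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class SamplingRateError(PeriSeizureError):
    """Sampling rate too low for the requested filters."""


class WindowError(PeriSeizureError):
    """Requested analysis window falls outside the recording or is too short."""


class DegenerateBaselineError(PeriSeizureError):
    """Baseline standard deviation is zero; z-scoring undefined."""


class AlignmentError(PeriSeizureError):
    """Two series that must share a time grid do not."""


class SingularDesignError(PeriSeizureError):
    """Rank-deficient design matrix in a GLM fit."""


class SplitError(PeriSeizureError):
    """Too few rows to produce a valid train/validation split."""
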
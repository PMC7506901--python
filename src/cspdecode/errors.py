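"""Exception hierarchy for cspdecode.

All package-specific failures derive from :class:`CspDecodeError` so callers
can catch one base class at pipeline boundaries.
"""


class CspDecodeError(Exception):
    """Base class for all cspdecode errors."""


class DataError(CspDecodeError):
    """Input data violates a basic contract (non-finite values, bad shape)."""


class InvalidBandError(CspDecodeError):
    """A frequency band is empty, inverted, or exceeds the Nyquist limit."""


class EpochingError(CspDecodeError):
    """An epoch window falls outside the recording for one or more events."""


class DegenerateTrialError(CspDecodeError):
    """A trial carries no signal energy (zero-trace covariance)."""


class SingularCovarianceError(CspDecodeError):
    """A class covariance is numerically singular beyond ridge loading."""


class DegenerateFeatureError(CspDecodeError):
    """A projected channel has zero variance; log-variance is undefined."""


class PlanningError(CspDecodeError):
    """A wavelet decomposition plan cannot be built for the given rate."""


class DecompositionError(CspDecodeError):
    """A signal is too short for the requested wavelet decomposition."""


class FitError(CspDecodeError):
    """A classifier cannot be fitted (e.g. single-class training data)."""


class ConfigError(CspDecodeError):
    """A pipeline configuration is internally inconsistent."""
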
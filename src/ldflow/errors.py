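"""Typed exceptions raised across the toolkit."""


class LdflowError(Exception):
    """Base class for all toolkit errors."""


class InvalidFrameError(LdflowError):
    """A photocurrent frame violates its invariants (length, d.c. level, rate)."""


class ConfigurationError(LdflowError):
    """An acquisition or analysis setting is inconsistent (e.g. cut-off above Nyquist)."""


class EmptyBandError(LdflowError):
    """An integration band covers no spectral bins."""


class UndefinedSpeedError(LdflowError):
    """Mean-speed estimate requested on a band with zero spectral mass."""


class DegenerateSpectrumError(LdflowError):
    """The frequency-weighted spectrum sums to zero; no cumulative curve exists."""


class EmptyIntervalError(LdflowError):
    """A time window selects no spectra."""


class GridMismatchError(LdflowError):
    """Two spectra or curves do not share the same frequency grid."""


class EmptyStageError(LdflowError):
    """A protocol stage contains no samples."""


class MissingFeatureError(LdflowError):
    """A classifier requires a feature that is absent or non-finite."""


class LabelError(LdflowError):
    """Classification input does not contain exactly two classes."""


class SingularCovarianceError(LdflowError):
    """Pooled within-class covariance is singular and no ridge fallback was enabled."""


class FrameIOError(LdflowError):
    """A frame or spectra file is missing metadata, truncated, or inconsistent."""
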
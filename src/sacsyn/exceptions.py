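"""Exception hierarchy for sacsyn.

Every error raised by the library derives from :class:`SacsynError` so that
pipeline drivers can catch analysis failures without masking programming
errors.
"""


class SacsynError(Exception):
    """Base class for all sacsyn errors."""


class InvalidProtocolError(SacsynError):
    """Stimulus protocol violates its own invariants (e.g. cutoff >= Nyquist)."""


class DegenerateInputError(SacsynError):
    """An input signal carries no usable variance (zero stimulus, zero response)."""


class UndefinedCorrelationError(SacsynError):
    """A Pearson correlation is requested against a constant signal."""


class NoPeakError(SacsynError):
    """Filter metrics requested for a filter without a positive peak in window."""


class FitFailureError(SacsynError):
    """A nonlinear least-squares fit failed to converge or hit a hard bound."""


class InsufficientDataError(SacsynError):
    """Too few samples or events for the requested operation."""


class ResolutionError(SacsynError):
    """Sampling intervals of two signals do not match."""


class DegenerateKernelError(SacsynError):
    """Deconvolution kernel is identically zero."""


class InsufficientBaselineError(SacsynError):
    """Pre-stimulus baseline shorter than required for the noise estimate."""


class ThresholdUndefinedError(SacsynError):
    """Event-detection threshold undefined (zero baseline variance)."""


class DegenerateTraceError(SacsynError):
    """A trace with zero standard deviation where variance is required."""


class NormalizationError(SacsynError):
    """Spectrum normalization impossible (zero power at reference frequency)."""


class BinningError(SacsynError):
    """Histogram bin edges of inputs do not match."""


class SchemaError(SacsynError):
    """A stored session/trace is missing required metadata."""


class EmptyTraceError(SacsynError):
    """A trace table contains a header but no samples."""
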
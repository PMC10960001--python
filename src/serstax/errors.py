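"""Exception hierarchy for serstax.

Every error raised by the library derives from :class:`SerstaxError` so that
callers (and the CLI) can catch domain failures without swallowing plain bugs.
"""


class SerstaxError(Exception):
    """Base class for all serstax errors."""


class SpectrumParseError(SerstaxError):
    """A spectrum file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptySpectrumError(SerstaxError):
    """Fewer than two usable data points were found."""


class ValidationError(SerstaxError):
    """A domain object violates one of its invariants."""


class DegenerateInputError(SerstaxError):
    """Input is formally valid but carries no usable signal (e.g. a constant
    vector handed to min-max normalization, or a single-level calibration)."""


class CoverageError(SerstaxError):
    """A spectrum does not cover the requested wavenumber window."""


class NoPeakError(SerstaxError):
    """A search window contains no local intensity maximum."""


class BandRangeError(SerstaxError):
    """A requested band centre lies outside the spectrum."""


class PeakFitError(SerstaxError):
    """Peak fitting failed to converge.

    ``peaks`` holds the best-so-far parameters, ``residual_norm`` the L2 norm
    of the corresponding residual, so callers can inspect or accept them.
    """

    def __init__(self, message: str, peaks=None, residual_norm=None):
        super().__init__(message)
        self.peaks = peaks
        self.residual_norm = residual_norm


class TrainingError(SerstaxError):
    """A model stage cannot be trained from the given data."""


class SchemaError(SerstaxError):
    """Feature vector does not match the model's feature schema."""
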
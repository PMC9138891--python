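"""Exception hierarchy shared across the pipeline."""


class ExGaussWorkloadError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ExGaussWorkloadError, ValueError):
    """Invalid distribution or configuration parameters."""


class DataError(ExGaussWorkloadError, ValueError):
    """Input data violate a precondition."""


class TooFewObservationsError(DataError):
    """A series is shorter than the operation's minimum sample size."""


class DegenerateDataError(DataError):
    """A series has zero variance (or too few distinct values) to be usable."""


class LoadError(ExGaussWorkloadError):
    """A file could not be parsed; carries offending line numbers where known."""

    def __init__(self, message, lines=None):
        super().__init__(message)
        self.lines = tuple(lines) if lines is not None else ()


class SynchronizationError(ExGaussWorkloadError):
    """Eye-event and trial streams cannot be aligned on a common time axis."""
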
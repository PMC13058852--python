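"""Exception hierarchy shared across the pipeline."""


class FusiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FusiError, ValueError):
    """A configuration value violates its contract; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InputError(FusiError, ValueError):
    """Invalid data passed to an operation (shape, finiteness, emptiness)."""


class ParameterError(FusiError, ValueError):
    """A scalar parameter is out of its admissible range."""


class StrategyError(FusiError, ValueError):
    """A denoising strategy combines incompatible options."""


class GeometryError(FusiError, ValueError):
    """A region of interest does not intersect the voxel grid."""


class DegenerateSignalError(FusiError, ValueError):
    """A signal is too degenerate (constant, zero-baseline) for the metric."""


class RejectedAcquisitionError(FusiError, RuntimeError):
    """Acquisition discarded: too little data retained after scrubbing.

    Carries ``retained_seconds`` so callers can report how much survived.
    """

    def __init__(self, retained_seconds: float, minimum_seconds: float = 300.0):
        self.retained_seconds = float(retained_seconds)
        self.minimum_seconds = float(minimum_seconds)
        super().__init__(
            f"acquisition rejected: {retained_seconds:.1f} s retained after "
            f"scrubbing, below the {minimum_seconds:.0f} s minimum"
        )
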
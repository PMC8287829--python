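"""Exception hierarchy shared across the package."""


class FibroEgmError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FibroEgmError, ValueError):
    """Invalid user-supplied parameter (dimensions, heights, band edges, ...)."""


class DataError(FibroEgmError, ValueError):
    """Input data violates a precondition (schema mismatch, too few segments, ...)."""


class ConvergenceError(FibroEgmError, RuntimeError):
    """Iterative procedure (fiber placement, calibration) failed to converge."""


class CalibrationError(ConvergenceError):
    """Conduction-velocity target unreachable within the allowed scale bounds."""


class StabilityError(FibroEgmError, RuntimeError):
    """Numerical blow-up of the reaction-diffusion integration."""


class MeasurementError(FibroEgmError, RuntimeError):
    """A probe/trace measurement could not be made (no activation, zero delay)."""


class ModelError(FibroEgmError, ValueError):
    """An autoregressive model is unusable (unstable, degenerate)."""


class NoActivityError(FibroEgmError, RuntimeError):
    """No activity segment was detected; the trace is unusable for features."""
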
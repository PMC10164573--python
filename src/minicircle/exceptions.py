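"""Exception hierarchy for the minicircle package."""


class MinicircleError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MinicircleError, ValueError):
    """A scalar parameter is outside its physical domain."""


class TopologyError(MinicircleError):
    """Operation requires a closed (or closed, self-avoiding) curve."""


class StericViolationError(MinicircleError):
    """Centerline approaches itself closer than the steric thickness."""


class ConfigurationError(MinicircleError):
    """Inconsistent model configuration (e.g. bead spacing exceeds diameter)."""


class BuoyancyError(MinicircleError):
    """Particle is neutrally buoyant or floats (v̄·ρ ≥ 1)."""


class FitError(MinicircleError):
    """Calibration/least-squares fit cannot be performed."""


class NumericalError(MinicircleError):
    """A linear-algebra or quadrature step failed to produce a usable result."""
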
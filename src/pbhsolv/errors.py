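"""Exception hierarchy for pbhsolv."""


class PBHSolvError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PBHSolvError, ValueError):
    """A physical parameter violates its domain (e.g. l_s <= 0)."""


class ShapeMismatchError(PBHSolvError, ValueError):
    """Per-site arrays of a lattice configuration have inconsistent lengths."""


class DegenerateProfileError(PBHSolvError, ValueError):
    """A potential profile is too coarse to bracket an extremum."""


class NumericalBlowupError(PBHSolvError, RuntimeError):
    """A simulated field exceeded the magnitude guard (time step too large)."""


class NoGrowthDetectedError(PBHSolvError, RuntimeError):
    """No exponential growth of the probed Fourier mode was detected."""


class AllZeroFrameError(PBHSolvError, ValueError):
    """A charge-density frame is identically zero."""


class InterpolationFailureError(PBHSolvError, RuntimeError):
    """Polynomial reconstruction of the determinant failed to converge."""


class RootRefinementError(PBHSolvError, RuntimeError):
    """A dispersion root could not be polished to the residual bound."""


class UnknownModeError(PBHSolvError, ValueError):
    """Unknown perturbation-matrix mode (expected 'printed' or 'derived')."""


class ConfigError(PBHSolvError, ValueError):
    """Configuration parsing or schema validation failed."""


class UnknownFixtureError(ConfigError):
    """A named fixture does not exist in the registry."""
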
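"""Exception and warning types shared across the package."""


class IsostimError(Exception):
    """Base class for all package errors."""


class NoFixedPointError(IsostimError):
    """Root search failed to locate a fixed point from any start."""


class MultipleFixedPointsWarning(UserWarning):
    """Distinct fixed points were found; the stable focus was returned."""


class NotAFocusError(IsostimError):
    """Fixed point does not have a complex eigenvalue pair with negative real part."""


class IntegrationError(IsostimError):
    """Trajectory became non-finite during integration."""


class DivergenceError(IsostimError):
    """Trajectory left the configured bounding box (point outside basin)."""


class DegenerateEigenbasisError(IsostimError):
    """|b2*a1 - b1*a2| below tolerance; observables are degenerate."""


class SeriesTooShortError(IsostimError):
    """Time series too short for the requested transform."""


class EmptyFieldError(IsostimError):
    """Amplitude field has no unmasked bins."""


class GridMismatchError(IsostimError):
    """Two fields do not share the same grid."""


class DegenerateWindowError(IsostimError):
    """Discounting window has zero length (n1 == n0)."""


class NoMatchError(IsostimError):
    """Derivative-free search exhausted its budget without entering tolerance."""

    def __init__(self, message, best_magnitude=None, best_power=None):
        super().__init__(message)
        self.best_magnitude = best_magnitude
        self.best_power = best_power


class ConfigMismatchError(IsostimError):
    """Efficacy reports being compared were not produced under matched settings."""


class FixtureSearchExhaustedError(IsostimError):
    """Rejection sampling failed to find a model within the attempt budget."""
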
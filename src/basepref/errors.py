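"""Exception types shared across the pipeline."""


class BasePrefError(Exception):
    """Base class for all package errors."""


class UnsampleableWindowError(BasePrefError):
    """Biased density underflows to zero everywhere on the domain."""


class EmptyWindowError(BasePrefError):
    """A window contributed zero in-range samples to the histograms."""


class DisconnectedWindowsError(BasePrefError):
    """Adjacent window histograms share no populated bin; WHAM cannot join them."""


class NonConvergenceError(BasePrefError):
    """WHAM self-consistency loop hit max_iter; carries the last residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"WHAM did not converge in {iterations} iterations "
            f"(last residual {residual:.3e})"
        )


class IncompleteProfileError(BasePrefError):
    """PMF has unsampled bins inside the bound region [grid start, r_c]."""


class InconsistentFixtureError(BasePrefError):
    """Requested snapshot geometry violates the requested mode's criteria."""


class LayoutError(BasePrefError):
    """Toy-complex spec cannot be placed without steric overlap."""


class GeometryError(BasePrefError):
    """Malformed geometric annotation (e.g. ring with < 3 atoms)."""


class NoNucleobaseError(BasePrefError):
    """Structure contains no recognizable modified/standard nucleobase site."""
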
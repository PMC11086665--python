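"""Exception hierarchy.

All toolkit errors derive from :class:`CTTextureError` so callers can catch
one base class; the leaves distinguish precondition failures (dimension,
alignment, insufficient data) from numerical failures (degenerate input,
fit failure) and geometric failures (non-elliptical conic, no intersection).
"""


class CTTextureError(Exception):
    """Base class for all cttexture errors."""


class DimensionError(CTTextureError, ValueError):
    """Array shape does not meet a structural precondition (e.g. non-square grid)."""


class InsufficientDataError(CTTextureError, ValueError):
    """Too few slices / samples / points for the requested operation."""


class DegenerateInputError(CTTextureError, ValueError):
    """Input carries no usable signal (all-zero curve, constant stack, zero area)."""


class DomainError(CTTextureError, ValueError):
    """A scalar argument lies outside its mathematical domain."""


class FitFailureError(CTTextureError, RuntimeError):
    """No optimizer start converged; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class AlignmentError(CTTextureError, ValueError):
    """Two sampled curves or grids do not share a common axis."""


class CoverageError(CTTextureError, ValueError):
    """A 1-D spectrum does not cover the frequency support of the requested grid."""


class InfeasibleTargetError(CTTextureError, ValueError):
    """No model parameters realize the requested (f_peak, sigma) target."""


class RegularizationRequiredError(CTTextureError, ValueError):
    """A spectral inverse is singular; a positive epsilon is required."""


class DivisionGuardError(CTTextureError, ZeroDivisionError):
    """Unregularized spectral inversion hit a zero bin."""


class GeometryError(CTTextureError, ValueError):
    """A geometric construction (chord, intersection) does not exist."""


class NonEllipticalError(CTTextureError, ValueError):
    """The best-fit conic is not an ellipse; carries the conic coefficients."""

    def __init__(self, message: str, conic=None):
        super().__init__(message)
        self.conic = conic
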
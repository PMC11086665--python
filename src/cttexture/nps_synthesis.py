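"""Noise synthesis with a prescribed NPS.

Workflow: a target ``(f_peak, sigma)`` pair is mapped to the reduced-model
parameters ``(alpha, beta)`` (the peak constraint eliminates beta
analytically, a 1-D root search over alpha matches the downslope sigma); the
1-D curve is revolved into a radially symmetric 2-D spectrum on a pixel grid;
white Gaussian noise is filtered in the Fourier domain with the square root
of that spectrum (so the realized power spectrum equals the prescribed one)
and rescaled to a sample-exact mean and standard deviation.

A literal variant that filters with the spectrum itself instead of its square
root is available via ``filter_convention="literal"``; it produces noise whose
measured power spectrum is the square of the prescribed shape, so the default
is the square-root convention under which the synthesis/estimation round trip
closes.

The default pixel spacing is 0.0625 cm (Nyquist 8 lp/cm), wide enough to
cover lung-kernel spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import (
    CoverageError,
    DegenerateInputError,
    DimensionError,
    InfeasibleTargetError,
)
from .nps_core import NPS1D, ImageStack, normalize_unit_area
from .nps_models import (
    fit_half_gaussian_sigma,
    fpeak_analytic,
    three_param_model,
)

__all__ = [
    "DEFAULT_PIXEL_SPACING_CM",
    "NPS2D",
    "NoisePatch",
    "model_nps1d",
    "solve_model_params",
    "build_nps2d",
    "synthesize_noise",
    "generate_phantom_stack",
]

DEFAULT_PIXEL_SPACING_CM = 0.0625  # Nyquist 8 lp/cm
_DEFAULT_CURVE_SAMPLES = 1025


@dataclass(frozen=True)
class NPS2D:
    """Radially symmetric 2-D noise power spectrum on a square pixel grid.

    ``values`` is in FFT layout (DC at ``[0, 0]``); the DC bin is zero.
    """

    values: np.ndarray
    pixel_spacing_cm: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("2-D spectrum must be square")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width(self) -> float:
        """Frequency step of the grid in lp/cm."""
        return 1.0 / (self.grid_size * self.pixel_spacing_cm)


@dataclass(frozen=True)
class NoisePatch:
    """A 2-D colored-noise image with sample-exact mean and SD."""

    values: np.ndarray
    mean_target: float
    sd_target: float
    seed: object = None
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def model_nps1d(alpha: float, beta: float, *, a: float = 1.0,
                pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                n_samples: int = _DEFAULT_CURVE_SAMPLES,
                normalized: bool = True) -> NPS1D:
    """Sample the reduced model on a uniform grid from 0 to Nyquist."""
    nyq = 1.0 / (2.0 * pixel_spacing_cm)
    f = np.linspace(0.0, nyq, n_samples)
    if normalized:
        # evaluate in log space so extreme (alpha, beta) do not underflow to
        # an all-zero curve before the unit-area rescale
        with np.errstate(divide="ignore"):
            logv = np.log(f) - (f - alpha) ** 2 / (2.0 * beta ** 2)
        v = np.exp(logv - logv[1:].max())
        v[0] = 0.0
        nps = NPS1D(f, v, pixel_spacing_cm)
        return normalize_unit_area(nps)
    v = three_param_model(f, a, alpha, beta)
    return NPS1D(f, np.maximum(v, 0.0), pixel_spacing_cm)


def _sigma_of_alpha(alpha: float, f_peak: float,
                    pixel_spacing_cm: float, n_samples: int) -> float:
    from .errors import FitFailureError

    beta = np.sqrt(f_peak * (f_peak - alpha))
    curve = model_nps1d(alpha, beta, pixel_spacing_cm=pixel_spacing_cm,
                        n_samples=n_samples)
    try:
        half = fit_half_gaussian_sigma(curve, f_peak)
    except FitFailureError:
        # spike narrower than the sampling grid: below any measurable width
        return 0.0
    if half is None:
        return np.inf
    return half.sigma


def solve_model_params(f_peak_target: float, sigma_target: float, *,
                       pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                       n_samples: int = _DEFAULT_CURVE_SAMPLES,
                       tol: float = 1e-8) -> tuple[float, float]:
    """Find (alpha, beta) of the reduced model matching a (f_peak, sigma) target.

    The peak constraint gives ``beta**2 = f_peak * (f_peak - alpha)`` in
    closed form (requires ``alpha < f_peak``), leaving a 1-D root search over
    alpha so that the half-Gaussian fitted through the generated curve's
    downslope has width ``sigma_target``.
    """
    if f_peak_target <= 0:
        raise InfeasibleTargetError("f_peak target must be positive")
    if sigma_target <= 0:
        raise InfeasibleTargetError("sigma target must be positive")
    nyq = 1.0 / (2.0 * pixel_spacing_cm)
    if f_peak_target >= nyq:
        raise InfeasibleTargetError(
            f"f_peak target {f_peak_target:g} must lie below Nyquist {nyq:g}")

    def resid(alpha):
        return _sigma_of_alpha(alpha, f_peak_target,
                               pixel_spacing_cm, n_samples) - sigma_target

    hi = f_peak_target - 1e-6 * max(f_peak_target, 1.0)
    r_hi = resid(hi)  # narrowest feasible curve: sigma -> small
    if r_hi > 0:
        raise InfeasibleTargetError(
            f"sigma target {sigma_target:g} below the narrowest achievable width")
    lo = f_peak_target - 2.0
    r_lo = resid(lo)
    for _ in range(40):
        if r_lo > 0:
            break
        lo = f_peak_target - 2.0 * (f_peak_target - lo)
        r_lo = resid(lo)
    else:
        raise InfeasibleTargetError(
            f"sigma target {sigma_target:g} above the widest achievable width")
    alpha = brentq(resid, lo, hi, xtol=tol)
    beta = float(np.sqrt(f_peak_target * (f_peak_target - alpha)))
    # consistency: the analytic peak must reproduce the target
    assert abs(fpeak_analytic(alpha, beta) - f_peak_target) < 1e-6
    return float(alpha), beta


def build_nps2d(nps: NPS1D, grid_size: int,
                pixel_spacing_cm: float | None = None) -> NPS2D:
    """Revolve a 1-D spectrum into a radially symmetric 2-D spectrum.

    Each 2-D frequency bin takes the linearly interpolated 1-D value at its
    radial frequency; radii beyond the 1-D curve's Nyquist (the grid corners)
    are set to zero, as is the DC bin.
    """
    s = nps.pixel_spacing_cm if pixel_spacing_cm is None else pixel_spacing_cm
    axis_nyq = 1.0 / (2.0 * s)
    if axis_nyq > nps.frequencies[-1] * (1.0 + 1e-9):
        raise CoverageError(
            f"grid Nyquist {axis_nyq:g} exceeds the 1-D curve's range "
            f"{nps.frequencies[-1]:g}")
    fx = np.fft.fftfreq(grid_size, d=s)
    r = np.hypot(fx[:, None], fx[None, :])
    vals = np.interp(r, nps.frequencies, nps.values, right=0.0)
    vals[r > nps.frequencies[-1]] = 0.0
    vals[0, 0] = 0.0
    return NPS2D(vals, s)


def synthesize_noise(nps2d: NPS2D, mu: float, sd: float, seed, *,
                     filter_convention: str = "sqrt") -> NoisePatch:
    """Realize a colored-noise patch with the prescribed 2-D spectrum.

    Seeded unit white Gaussian noise is filtered in the Fourier domain —
    by ``sqrt(NPS2D)`` under the default convention, so the realized power
    spectrum equals ``NPS2D``, or by ``NPS2D`` itself under the "literal"
    convention — then rescaled to sample-exact mean ``mu`` and SD ``sd``.
    """
    if filter_convention not in ("sqrt", "literal"):
        raise ValueError("filter_convention must be 'sqrt' or 'literal'")
    if not np.any(nps2d.values > 0):
        raise DegenerateInputError("2-D spectrum has no energy")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(nps2d.values.shape)
    filt = np.sqrt(nps2d.values) if filter_convention == "sqrt" else nps2d.values
    colored = np.fft.ifft2(np.fft.fft2(white) * filt).real
    std = colored.std()
    if std == 0.0:
        raise DegenerateInputError("synthesized field is constant")
    out = (colored - colored.mean()) / std * sd + mu
    return NoisePatch(out, mean_target=mu, sd_target=sd, seed=seed,
                      metadata={"filter_convention": filter_convention,
                                "pixel_spacing_cm": nps2d.pixel_spacing_cm})


def generate_phantom_stack(nps: NPS1D, n_slices: int, size: int = 128,
                           seed=0, *, mu: float = 0.0,
                           sd: float | None = None) -> ImageStack:
    """Generate a stack of independent colored-noise slices from a 1-D NPS.

    Stands in for a homogeneous-phantom acquisition when validating the NPS
    estimation round trip.  Per-slice seeds are derived from the master seed
    by a counter-based scheme, so slice ``i`` is reproducible independently
    of generation order.  When ``sd`` is None the slice SD is chosen so the
    stack's unnormalized spectrum matches the input curve's absolute scale
    (Parseval: variance = 2-D spectral integral).
    """
    nps2d = build_nps2d(nps, size)
    if sd is None:
        sd = float(np.sqrt(np.sum(nps2d.values) * nps2d.bin_width ** 2))
        if sd == 0.0:
            raise DegenerateInputError("spectrum has no energy")
    slices = np.empty((n_slices, size, size))
    for i in range(n_slices):
        child = np.random.SeedSequence([int(seed), i])
        slices[i] = synthesize_noise(nps2d, mu, sd, child).values
    return ImageStack(slices, nps.pixel_spacing_cm,
                      metadata={"seed": int(seed), "mu": mu, "sd": sd,
                                "n_slices": n_slices})
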
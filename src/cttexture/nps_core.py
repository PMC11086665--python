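"""1-D noise power spectra: containers, estimation from image stacks, normalization.

The CT noise power spectrum (NPS) is estimated from a stack of noise-only
slices (e.g. water-phantom acquisitions): the central ROI of each slice is
mean-subtracted, its 2-D periodogram is computed, the periodograms are
averaged over slices and collapsed to a radial 1-D profile.  Frequencies are
in line pairs per centimeter (lp/cm, equivalently cycles/cm).

Periodogram scaling is ``|FFT|^2 * pixel_spacing_cm^2 / n_pixels`` so that the
2-D integral of the spectrum (sum times the squared frequency-bin width)
equals the per-slice pixel variance exactly (Parseval), giving units of
HU^2 cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionError,
    InsufficientDataError,
)

__all__ = [
    "NPS1D",
    "ImageStack",
    "estimate_nps1d",
    "periodogram_2d",
    "radial_average",
    "normalize_unit_area",
]


@dataclass(frozen=True)
class NPS1D:
    """A sampled radial 1-D noise power spectrum.

    Parameters
    ----------
    frequencies : ndarray
        Monotonically increasing grid in lp/cm, starting at 0 and ending at
        the Nyquist frequency ``1 / (2 * pixel_spacing_cm)``.
    values : ndarray
        Nonnegative spectral density per frequency sample.
    pixel_spacing_cm : float
        Pixel spacing of the originating image grid, in cm.
    normalized : bool
        True when the trapezoidal area under the curve is 1.
    """

    frequencies: np.ndarray
    values: np.ndarray
    pixel_spacing_cm: float
    normalized: bool = False

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.ndim != 1 or v.shape != f.shape:
            raise DimensionError("frequencies and values must be matching 1-D arrays")
        if f.size < 2:
            raise DimensionError("an NPS needs at least two frequency samples")
        if f[0] != 0.0:
            raise ValueError("frequency axis must start at 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectral values must be nonnegative")
        nyq = 1.0 / (2.0 * self.pixel_spacing_cm)
        if not np.isclose(f[-1], nyq, rtol=1e-6):
            raise ValueError(
                f"last frequency {f[-1]:g} must equal the Nyquist frequency {nyq:g}"
            )
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_spacing_cm)

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.values, self.frequencies))

    def interpolate(self, freq: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve; zero beyond the Nyquist frequency."""
        return np.interp(np.asarray(freq, dtype=float), self.frequencies, self.values,
                         left=self.values[0], right=0.0)

    def with_values(self, values: np.ndarray, *, normalized: bool | None = None) -> "NPS1D":
        return replace(self, values=np.asarray(values, dtype=float),
                       normalized=self.normalized if normalized is None else normalized)


@dataclass(frozen=True)
class ImageStack:
    """A slice-indexed stack of 2-D images (HU) with common pixel spacing."""

    data: np.ndarray  # shape (n_slices, rows, cols)
    pixel_spacing_cm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise DimensionError("stack data must be (n_slices, rows, cols)")
        if d.shape[0] < 1:
            raise InsufficientDataError("stack must contain at least one slice")
        object.__setattr__(self, "data", d)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def _central_roi(img: np.ndarray, roi_size: int) -> np.ndarray:
    r0 = (img.shape[0] - roi_size) // 2
    c0 = (img.shape[1] - roi_size) // 2
    return img[r0:r0 + roi_size, c0:c0 + roi_size]


def periodogram_2d(stack: ImageStack, roi_size: int = 128,
                   min_slices: int = 100) -> np.ndarray:
    """Slice-averaged 2-D periodogram of the mean-subtracted central ROI.

    Returns the 2-D NPS in FFT layout (DC at index ``[0, 0]``), scaled so that
    its integral over 2-D frequency equals the mean per-slice ROI variance.
    """
    if roi_size > min(stack.shape):
        raise DimensionError(
            f"ROI {roi_size} exceeds slice shape {stack.shape}")
    if stack.n_slices < min_slices:
        raise InsufficientDataError(
            f"{stack.n_slices} slices < required {min_slices}")
    s = stack.pixel_spacing_cm
    acc = np.zeros((roi_size, roi_size))
    any_signal = False
    for sl in stack.data:
        roi = _central_roi(sl, roi_size)
        roi = roi - roi.mean()
        if np.any(roi):
            any_signal = True
        acc += np.abs(np.fft.fft2(roi)) ** 2
    if not any_signal:
        raise DegenerateInputError("stack has zero variance in the ROI")
    return acc * (s * s / roi_size ** 2) / stack.n_slices


def radial_average(power2d: np.ndarray, pixel_spacing_cm: float) -> NPS1D:
    """Collapse a square 2-D power grid (FFT layout) to a radial 1-D profile.

    Bins have the FFT's native frequency step ``1 / (n * pixel_spacing_cm)``;
    a pixel contributes to the bin nearest its radial frequency.  Frequencies
    beyond the axis Nyquist (grid corners) are discarded.  Empty bins are
    filled by linear interpolation from their neighbors.
    """
    p = np.asarray(power2d, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise DimensionError("power grid must be square")
    n = p.shape[0]
    df = 1.0 / (n * pixel_spacing_cm)
    fx = np.fft.fftfreq(n, d=pixel_spacing_cm)
    r = np.hypot(fx[:, None], fx[None, :])
    idx = np.rint(r / df).astype(int)
    nbins = n // 2 + 1
    mask = idx < nbins
    counts = np.bincount(idx[mask], minlength=nbins)[:nbins]
    sums = np.bincount(idx[mask], weights=p[mask], minlength=nbins)[:nbins]
    values = np.zeros(nbins)
    filled = counts > 0
    values[filled] = sums[filled] / counts[filled]
    if not filled.all():
        bins = np.arange(nbins)
        values[~filled] = np.interp(bins[~filled], bins[filled], values[filled])
    freqs = np.arange(nbins) * df
    return NPS1D(freqs, np.maximum(values, 0.0), pixel_spacing_cm)


def estimate_nps1d(stack: ImageStack, roi_size: int = 128,
                   min_slices: int = 100) -> NPS1D:
    """Estimate the radial 1-D NPS of a noise stack.

    Per-slice 2-D periodogram of the mean-subtracted central ROI, averaged
    over slices and radially averaged.  The result is unnormalized
    (HU^2 cm^2); pass it through :func:`normalize_unit_area` for the
    shape-only unit-area form.
    """
    p2 = periodogram_2d(stack, roi_size=roi_size, min_slices=min_slices)
    return radial_average(p2, stack.pixel_spacing_cm)


def normalize_unit_area(nps: NPS1D) -> NPS1D:
    """Rescale a spectrum to unit trapezoidal area under the curve."""
    area = nps.area()
    if area <= 0.0:
        raise DegenerateInputError("cannot normalize a curve with zero area")
    if nps.normalized and np.isclose(area, 1.0, atol=1e-12):
        return nps
    return nps.with_values(nps.values / area, normalized=True)
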
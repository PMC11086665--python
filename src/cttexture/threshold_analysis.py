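"""Threshold-ellipse geometry and iso-frequency curves.

The eight per-direction detectability thresholds define points in
(f_peak, sigma) space; a conic is least-squares fitted through them and
converted to ellipse form (center, semi-axes, major-axis angle).  The default
fit minimizes the algebraic residual under the Bookstein normalization
``A^2 + B^2/2 + C^2 = 1``, which is invariant under rigid motions of the
plane, so the fitted geometry is equivariant under translation and rotation
of the points; it raises if the best conic is not an ellipse.  The
Fitzgibbon ellipse-specific constraint (``4AC - B^2 = 1``), which can never
return a hyperbola, is available via ``method="fitzgibbon"`` for noisy data.

Angles are measured counterclockwise from the +f_peak axis with equal axis
scaling (both axes in lp/cm); plotting with unequal aspect changes apparent
angles, not these numbers.

Per-parameter thresholds come from chords: the f_peak detectability threshold
at the reference sigma is half the length of the ellipse's horizontal chord
at that sigma.  Iso-f_av curves — the locus of (f_peak, sigma) whose model
NPS keeps the reference's average frequency — are traced by root-finding on
sigma at each f_peak.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (
    GeometryError,
    InfeasibleTargetError,
    InsufficientDataError,
    NonEllipticalError,
)
from .nps_models import TwoParamDescriptor, average_frequency
from .nps_synthesis import DEFAULT_PIXEL_SPACING_CM, model_nps1d, solve_model_params

__all__ = [
    "REFERENCE_DESCRIPTORS",
    "ThresholdEllipse",
    "fit_threshold_ellipse",
    "ellipse_fpeak_threshold",
    "iso_fav_curve",
    "iso_fpeak_line",
    "load_table_thresholds",
    "threshold_points",
]

# (f_peak, sigma) in lp/cm of the two reference spectra (body / lung
# reconstruction kernels, hybrid iterative reconstruction).
REFERENCE_DESCRIPTORS: dict[str, tuple[float, float]] = {
    "body": (1.89, 1.28),
    "lung": (4.64, 1.83),
}


@dataclass(frozen=True)
class ThresholdEllipse:
    """An ellipse in (f_peak, sigma) space, conic and axes forms."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float  # major axis vs +f_peak axis, [0, 180), equal scaling
    residual: float
    conic: tuple[float, float, float, float, float, float]

    def evaluate_conic(self, x, y):
        a, b, c, d, e, f = self.conic
        return a * x * x + b * x * y + c * y * y + d * x + e * y + f


def _fit_conic_bookstein(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # minimize ||conic residual|| s.t. A^2 + B^2/2 + C^2 = 1 (rigid-motion
    # invariant); linear part eliminated by least squares, quadratic part from
    # the smallest singular vector of the reduced design matrix.
    d1 = np.column_stack([x * x, np.sqrt(2.0) * x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    q = np.linalg.lstsq(d2, d1, rcond=None)[0]
    reduced = d1 - d2 @ q
    _, _, vt = np.linalg.svd(reduced)
    w1 = vt[-1]
    w2 = -q @ w1
    return np.array([w1[0], np.sqrt(2.0) * w1[1], w1[2], w2[0], w2[1], w2[2]])


def _fit_conic_fitzgibbon(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # Halir & Flusser numerically stable formulation of the Fitzgibbon
    # ellipse-specific fit (constraint 4AC - B^2 = 1).
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    _, evecs = np.linalg.eig(m)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = cond > 0
    if not ok.any():
        raise NonEllipticalError("no elliptical solution found")
    a1 = evecs[:, ok][:, 0]
    return np.concatenate([a1, t @ a1])


def _conic_to_geometry(coef: np.ndarray):
    a, b, c, d, e, f = coef
    disc = b * b - 4.0 * a * c
    if disc >= 0:
        raise NonEllipticalError("best-fit conic is not an ellipse",
                                 conic=tuple(coef))
    m = np.array([[a, b / 2.0], [b / 2.0, c]])
    center = np.linalg.solve(2.0 * m, [-d, -e])
    f_c = float(coef @ np.array([center[0] ** 2, center[0] * center[1],
                                 center[1] ** 2, center[0], center[1], 1.0]))
    evals, evecs = np.linalg.eigh(m)
    with np.errstate(invalid="raise"):
        try:
            axes = np.sqrt(-f_c / evals)
        except FloatingPointError as exc:
            raise NonEllipticalError("degenerate (imaginary) ellipse",
                                     conic=tuple(coef)) from exc
    i_major = int(np.argmax(axes))
    angle = np.degrees(np.arctan2(evecs[1, i_major], evecs[0, i_major])) % 180.0
    return (float(center[0]), float(center[1])), float(np.max(axes)), \
        float(np.min(axes)), float(angle)


def fit_threshold_ellipse(points, method: str = "bookstein") -> ThresholdEllipse:
    """Least-squares ellipse through >= 5 (f_peak, sigma) points.

    ``method="bookstein"`` (default): generic-conic algebraic fit with a
    rigid-motion-invariant normalization; raises NonEllipticalError if the
    best conic is a hyperbola/parabola.  ``method="fitzgibbon"``: direct
    ellipse-constrained fit that always returns an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("points must be an (n, 2) array")
    if pts.shape[0] < 5:
        raise InsufficientDataError("an ellipse fit needs at least 5 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise InsufficientDataError("points are collinear")
    x, y = pts[:, 0], pts[:, 1]
    if method == "bookstein":
        coef = _fit_conic_bookstein(x, y)
    elif method == "fitzgibbon":
        coef = _fit_conic_fitzgibbon(x, y)
    else:
        raise ValueError("method must be 'bookstein' or 'fitzgibbon'")
    center, major, minor, angle = _conic_to_geometry(coef)
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    residual = float(np.sqrt(np.mean((design @ coef) ** 2)))
    return ThresholdEllipse(center=center, semi_major=major, semi_minor=minor,
                            angle_deg=angle, residual=residual,
                            conic=tuple(float(v) for v in coef))


def ellipse_fpeak_threshold(ellipse: ThresholdEllipse, ref_sigma: float) -> float:
    """Half the horizontal (f_peak-direction) chord at sigma = ref_sigma."""
    a, b, c, d, e, f = ellipse.conic
    qb = b * ref_sigma + d
    qc = c * ref_sigma * ref_sigma + e * ref_sigma + f
    disc = qb * qb - 4.0 * a * qc
    if disc <= 0:
        raise GeometryError(
            f"the line sigma = {ref_sigma:g} does not intersect the ellipse")
    return float(np.sqrt(disc) / (2.0 * abs(a)))


def iso_fpeak_line(ref, sigma_span) -> np.ndarray:
    """The vertical iso-f_peak line through the reference point."""
    fp = ref.f_peak if isinstance(ref, TwoParamDescriptor) else float(ref[0])
    sig = np.asarray(sigma_span, dtype=float)
    return np.column_stack([np.full_like(sig, fp), sig])


@dataclass(frozen=True)
class IsoFavCurve:
    points: np.ndarray  # (n, 2) array of (f_peak, sigma)
    f_av: float
    truncated: bool


def _fav_of(fp: float, sigma: float, pixel_spacing_cm: float) -> float:
    alpha, beta = solve_model_params(fp, sigma,
                                     pixel_spacing_cm=pixel_spacing_cm)
    return average_frequency(model_nps1d(alpha, beta,
                                         pixel_spacing_cm=pixel_spacing_cm))


def iso_fav_curve(ref, span, *,
                  pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM,
                  sigma_bracket: tuple[float, float] = (0.05, 6.0),
                  tol: float = 1e-4) -> IsoFavCurve:
    """Trace the locus of (f_peak, sigma) with the reference's f_av.

    For each f_peak in ``span``, solves for the sigma whose generated model
    NPS has the reference average frequency.  f_peak values where no sigma in
    the bracket achieves the target are dropped and the curve flagged
    truncated.
    """
    if isinstance(ref, TwoParamDescriptor):
        fav_target = ref.f_av
    else:
        fav_target = _fav_of(float(ref[0]), float(ref[1]), pixel_spacing_cm)
    pts = []
    truncated = False
    for fp in np.asarray(span, dtype=float):
        def g(sig, fp=fp):
            return _fav_of(fp, sig, pixel_spacing_cm) - fav_target

        lo, hi = sigma_bracket
        try:
            glo = g(lo)
        except InfeasibleTargetError:
            truncated = True
            continue
        ghi = None
        while hi > lo * 1.01:
            try:
                ghi = g(hi)
                break
            except InfeasibleTargetError:
                hi *= 0.8
        if ghi is None:
            truncated = True
            continue
        if glo * ghi > 0:
            truncated = True
            continue
        sigma = brentq(g, lo, hi, xtol=tol)
        pts.append((fp, sigma))
    if not pts:
        raise GeometryError("no point of the span admits the target f_av")
    return IsoFavCurve(points=np.asarray(pts), f_av=float(fav_target),
                       truncated=truncated)


def load_table_thresholds(kernel: str):
    """Average nonradiologist per-direction thresholds for a reference kernel.

    Returns a DataFrame with columns direction, d_fpeak, d_sigma (lp/cm);
    pure-f_peak and pure-sigma directions carry 0 for the unchanged
    parameter.
    """
    import pandas as pd

    if kernel not in REFERENCE_DESCRIPTORS:
        raise KeyError(f"unknown kernel {kernel!r}; use 'body' or 'lung'")
    ref = importlib.resources.files("cttexture.data").joinpath(
        f"thresholds_{kernel}.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def threshold_points(kernel: str) -> np.ndarray:
    """Absolute (f_peak, sigma) threshold points: reference + per-direction deltas."""
    fp, sg = REFERENCE_DESCRIPTORS[kernel]
    df = load_table_thresholds(kernel)
    return np.column_stack([fp + df["d_fpeak"].to_numpy(),
                            sg + df["d_sigma"].to_numpy()])
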
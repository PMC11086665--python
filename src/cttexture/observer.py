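"""Texture contrast and observers for the 2AFC texture-matching task.

Two stationary Gaussian texture classes that share a mean differ only in
their covariances, which a Fourier basis diagonalizes into per-frequency
power spectra S1, S2.  The ideal observer's test statistic is the
log-likelihood ratio, which in the Fourier domain reduces to the weighted
periodogram sum

    lambda(g) = (1/M) * sum_k (1/S1[k] - 1/S2[k]) * |g_hat[k] - mu_hat[k]|^2

(performance-equivalent form; M = number of pixels).  ``llr_spatial`` is the
dense spatial-domain oracle that materializes the circulant covariances and
inverts them explicitly; it is only meant for small grids.

The magnitude of a texture difference is summarized by the texture contrast
C_texture = integral of |NPS2D_1 - NPS2D_2| over 2-D frequency.  By default
the discrete sum is weighted by the frequency-bin area so the value is stable
under grid refinement; the bare-sum convention is available via a flag.

Simulated observers stand in for humans: the ideal observer decides trials
from the LLR, and a psychometric observer answers correctly with probability
given by a 2AFC Weibull function of the stimulus difference magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import dft

from .errors import (
    AlignmentError,
    DivisionGuardError,
    RegularizationRequiredError,
)
from .nps_synthesis import NPS2D, NoisePatch

__all__ = [
    "SpectrumHypothesis",
    "c_texture",
    "llr_spatial",
    "llr_fourier",
    "IdealObserver",
    "PsychometricObserver",
    "weibull_2afc",
    "decide_2afc",
]


@dataclass(frozen=True)
class SpectrumHypothesis:
    """A stationary Gaussian texture class: diagonal spectrum + shared mean."""

    S: np.ndarray  # per-2-D-frequency-bin covariance spectrum, FFT layout
    mu: float = 0.0
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.S, dtype=float)
        if np.any(s < 0):
            raise ValueError("spectral entries must be nonnegative")
        object.__setattr__(self, "S", s)

    @classmethod
    def from_nps2d(cls, nps2d: NPS2D, sd: float, mu: float = 0.0,
                   label: str = "") -> "SpectrumHypothesis":
        """Covariance spectrum of patches synthesized from ``nps2d``.

        Scaled so the implied pixel variance ``(1/M) sum(S)`` equals ``sd**2``,
        matching patches rescaled to a sample-exact SD.
        """
        total = float(np.sum(nps2d.values))
        if total <= 0:
            raise ValueError("spectrum has no energy")
        m = nps2d.values.size
        return cls(nps2d.values * (sd * sd * m / total), mu=mu, label=label)


def c_texture(nps2d_1: NPS2D, nps2d_2: NPS2D, *,
              bin_area_weighted: bool = True) -> float:
    """Texture contrast: summed absolute 2-D spectral difference.

    With ``bin_area_weighted`` (default) the sum is multiplied by the squared
    frequency-bin width, approximating the continuous integral independently
    of grid resolution; without it the bare sum over bins is returned.
    """
    if nps2d_1.values.shape != nps2d_2.values.shape or not np.isclose(
            nps2d_1.pixel_spacing_cm, nps2d_2.pixel_spacing_cm):
        raise AlignmentError("spectra live on different grids")
    total = float(np.sum(np.abs(nps2d_1.values - nps2d_2.values)))
    if bin_area_weighted:
        total *= nps2d_1.bin_width ** 2
    return total


def _patch_values(patch) -> np.ndarray:
    return patch.values if isinstance(patch, NoisePatch) else np.asarray(patch, float)


def llr_spatial(patch, h1: SpectrumHypothesis, h2: SpectrumHypothesis) -> float:
    """Dense spatial-domain LLR oracle: ``x^T (Sigma1^-1 - Sigma2^-1) x``.

    Builds the full circulant covariances ``Sigma_i = (1/M) F* diag(S_i) F``
    and inverts them explicitly; quadratic memory in the pixel count, so use
    small grids only.
    """
    g = _patch_values(patch)
    if g.shape != h1.S.shape or g.shape != h2.S.shape:
        raise AlignmentError("patch and hypothesis grids differ")
    n = g.shape[0]
    m = g.size
    if np.any(h1.S == 0) or np.any(h2.S == 0):
        raise RegularizationRequiredError(
            "singular covariance: a zero spectral entry makes Sigma non-invertible")
    f1 = dft(n)
    fmat = np.kron(f1, f1)
    x = (g - h1.mu).ravel()
    out = 0.0
    for s_diag, sign in ((h1.S, 1.0), (h2.S, -1.0)):
        sigma = (fmat.conj().T * s_diag.ravel()) @ fmat / m
        out += sign * float(x @ np.linalg.solve(sigma.real, x))
    return out


def llr_fourier(patch, h1: SpectrumHypothesis, h2: SpectrumHypothesis,
                epsilon: float = 0.0, *, exclude_dc: bool = True) -> float:
    """Fourier-domain LLR with optional Tikhonov-style spectral regularization.

    ``(1/M) sum_k (1/(S1[k]+eps^2) - 1/(S2[k]+eps^2)) |g_hat[k]-mu_hat[k]|^2``.
    ``epsilon=0`` is allowed only when every included spectral entry is
    positive.  The DC bin is excluded by default: both hypotheses share the
    mean, so it carries no texture information.
    """
    g = _patch_values(patch)
    if g.shape != h1.S.shape or g.shape != h2.S.shape:
        raise AlignmentError("patch and hypothesis grids differ")
    m = g.size
    ghat = np.fft.fft2(g - h1.mu)
    power = np.abs(ghat) ** 2
    s1 = h1.S + epsilon ** 2
    s2 = h2.S + epsilon ** 2
    include = np.ones(g.shape, dtype=bool)
    if exclude_dc:
        include[0, 0] = False
    if np.any(s1[include] == 0) or np.any(s2[include] == 0):
        raise DivisionGuardError(
            "zero spectral entry with epsilon=0; pass a positive epsilon")
    return float(np.sum((1.0 / s1[include] - 1.0 / s2[include]) * power[include]) / m)


def weibull_2afc(x, threshold: float, slope: float = 3.5,
                 guess: float = 0.5):
    """2AFC Weibull psychometric function ``1 - (1-guess) exp(-(x/t)^k)``."""
    x = np.asarray(x, dtype=float)
    p = 1.0 - (1.0 - guess) * np.exp(-np.power(np.maximum(x, 0.0) / threshold, slope))
    return float(p) if p.ndim == 0 else p


@dataclass
class IdealObserver:
    """Decides 2AFC trials from the regularized Fourier-domain LLR.

    ``epsilon`` defaults to ``1e-6 * max spectral value`` at decision time.
    """

    epsilon: float | None = None

    kind = "ideal"

    def decide(self, ref_hypothesis, alt_a, alt_b, other_hypothesis,
               **_) -> int:
        eps = self.epsilon
        if eps is None:
            eps = 1e-6 * max(float(ref_hypothesis.S.max()),
                             float(other_hypothesis.S.max()))
        scores = [llr_fourier(alt, ref_hypothesis, other_hypothesis, eps)
                  for alt in (alt_a, alt_b)]
        # lambda is large when the patch fits the *other* hypothesis better;
        # the reference-matching alternative minimizes it.  Ties -> first.
        return 0 if scores[0] <= scores[1] else 1


@dataclass
class PsychometricObserver:
    """Answers correctly with Weibull probability of the stimulus magnitude.

    ``stimulus_map`` converts the trial's parameter offset vector
    ``(d_fpeak, d_sigma)`` into the scalar stimulus the psychometric function
    sees; the default is the Euclidean magnitude.
    """

    threshold: float
    slope: float = 3.5
    guess: float = 0.5
    stimulus_map: Callable[[np.ndarray], float] | None = None
    seed: object = None
    rng: np.random.Generator = field(init=False, repr=False)

    kind = "psychometric"

    def __post_init__(self):
        self.rng = np.random.default_rng(self.seed)

    def p_correct(self, offset_vector) -> float:
        v = np.asarray(offset_vector, dtype=float)
        x = float(np.hypot(*v)) if self.stimulus_map is None else float(
            self.stimulus_map(v))
        return weibull_2afc(x, self.threshold, self.slope, self.guess)

    def decide(self, ref_hypothesis, alt_a, alt_b, other_hypothesis, *,
               correct_index: int, offset_vector) -> int:
        if self.rng.random() < self.p_correct(offset_vector):
            return correct_index
        return 1 - correct_index


def decide_2afc(ref_hypothesis: SpectrumHypothesis, alt_a, alt_b,
                other_hypothesis: SpectrumHypothesis, observer, *,
                correct_index: int | None = None,
                offset_vector=None) -> int:
    """Return the index (0 or 1) of the alternative the observer picks.

    The ideal observer scores both alternatives with the LLR and picks the
    one favoring the reference hypothesis (ties go to the first).  The
    psychometric observer ignores pixel content and answers correctly with
    probability given by its psychometric function, which requires
    ``correct_index`` and ``offset_vector``.
    """
    if getattr(observer, "kind", None) == "psychometric":
        if correct_index is None or offset_vector is None:
            raise ValueError(
                "psychometric observers need correct_index and offset_vector")
    return observer.decide(ref_hypothesis, alt_a, alt_b, other_hypothesis,
                           correct_index=correct_index,
                           offset_vector=offset_vector)
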
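"""Parametric fits, the analytic peak, the downslope sigma, f_av, and RSAD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cttexture as ct
from cttexture.errors import AlignmentError, DegenerateInputError, DomainError
from cttexture.nps_models import six_param_model, three_param_model

from conftest import BODY, LUNG, SPACING


def curve(values, f=None):
    if f is None:
        f = np.linspace(0, 8, values.size)
    return ct.NPS1D(f, values, SPACING)


class TestFpeakAnalytic:
    @pytest.mark.parametrize("alpha,beta,expected", [
        (0.0, 1.0, 1.0),
        (2.0, 0.0, 2.0),
        (1.0, 1.0, (1 + np.sqrt(5)) / 2),
    ])
    def test_closed_form(self, alpha, beta, expected):
        assert ct.fpeak_analytic(alpha, beta) == pytest.approx(expected, abs=1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(DomainError):
            ct.fpeak_analytic(1.0, -0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(alpha=st.floats(-3.0, 5.0), beta=st.floats(0.05, 4.0))
    def test_matches_grid_argmax_of_model(self, alpha, beta):
        fp = ct.fpeak_analytic(alpha, beta)
        step = 1e-5
        f = np.arange(max(fp - 0.01, step), fp + 0.01, step)
        # log-space oracle: immune to exp underflow for narrow peaks
        logv = np.log(f) - (f - alpha) ** 2 / (2 * beta ** 2)
        assert abs(fp - f[np.argmax(logv)]) <= step


class TestFitThreeParam:
    def test_recovers_exact_model(self):
        f = np.linspace(0, 8, 256)
        nps = curve(three_param_model(f, 1.0, 1.5, 0.8), f)
        fit = ct.fit_three_param(nps)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(1.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.8, abs=1e-6)
        assert fit.r_squared >= 1 - 1e-10

    def test_flat_curve_scores_poorly_but_finitely(self):
        fit = ct.fit_three_param(curve(np.ones(64)))
        assert fit.r_squared < 0.9
        assert np.isfinite([fit.a, fit.alpha, fit.beta]).all()

    def test_zero_curve_rejected(self):
        with pytest.raises(DegenerateInputError):
            ct.fit_three_param(curve(np.zeros(64)))


class TestFitSixParam:
    def test_recovers_exact_model(self):
        f = np.linspace(0, 8, 513)
        nps = curve(six_param_model(f, 1.0, 1.3, 1.0, 2.0, 1.5, 0.8), f)
        fit = ct.fit_six_param(nps)
        for got, want in [(fit.a, 1.0), (fit.b, 1.3), (fit.c, 1.0),
                          (fit.d, 2.0), (fit.alpha, 1.5), (fit.beta, 0.8)]:
            assert got == pytest.approx(want, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nesting_never_worse_than_reduced_model(self, seed):
        rng = np.random.default_rng(seed)
        f = np.linspace(0, 8, 129)
        v = three_param_model(f, 1.0, rng.uniform(0, 3), rng.uniform(0.5, 2))
        v = np.maximum(v + 0.02 * rng.standard_normal(f.size) * v.max(), 0.0)
        nps = curve(v, f)
        assert ct.fit_six_param(nps).r_squared >= \
            ct.fit_three_param(nps).r_squared - 1e-12


class TestFindFpeakSmoothed:
    def test_smooth_unimodal_peak(self):
        f = np.linspace(0, 8, 257)
        nps = curve(np.exp(-((f - 2.0) ** 2)), f)
        assert ct.find_fpeak_smoothed(nps) == pytest.approx(2.0, abs=f[1] - f[0])

    def test_single_bin_spike_is_suppressed(self):
        f = np.linspace(0, 8, 257)
        v = np.exp(-((f - 2.0) ** 2))
        v[np.argmin(np.abs(f - 6.0))] = 1.5  # 1.5x the main peak, one bin wide
        assert ct.find_fpeak_smoothed(curve(v, f)) == pytest.approx(2.0, abs=0.1)

    def test_monotone_curve_peaks_at_nyquist(self):
        f = np.linspace(0, 8, 257)
        assert ct.find_fpeak_smoothed(curve(f.copy(), f)) == pytest.approx(8.0)


class TestHalfGaussianSigma:
    def test_exact_tail_recovered(self):
        f = np.linspace(0, 8, 257)
        fp, a_true, s_true = 2.0, 0.4, 1.5
        v = np.where(f < fp, a_true * f / fp,
                     a_true * np.exp(-((f - fp) ** 2) / (2 * s_true ** 2)))
        half = ct.fit_half_gaussian_sigma(curve(v, f), fp)
        assert half.sigma == pytest.approx(s_true, abs=1e-8)
        assert half.a_prime == pytest.approx(a_true, abs=1e-8)

    def test_matches_brute_force_sigma_scan(self):
        f = np.linspace(0, 8, 513)
        nps = curve(three_param_model(f, 1.0, 0.0, 1.0), f)
        fp = 1.0
        half = ct.fit_half_gaussian_sigma(nps, fp)
        # brute-force oracle: dense sigma grid, optimal amplitude per sigma
        ft, vt = f[f >= fp], nps.values[f >= fp]
        sigmas = np.linspace(0.3, 3.0, 27001)
        best_ssr, best_sigma = np.inf, None
        for s in sigmas:
            shape = np.exp(-((ft - fp) ** 2) / (2 * s * s))
            amp = float(shape @ vt / (shape @ shape))
            ssr = float(np.sum((amp * shape - vt) ** 2))
            if ssr < best_ssr:
                best_ssr, best_sigma = ssr, s
        assert half.sigma == pytest.approx(best_sigma, abs=1e-4)

    def test_ramp_only_curve_has_no_downslope(self):
        f = np.linspace(0, 8, 257)
        assert ct.fit_half_gaussian_sigma(curve(f.copy(), f), 8.0) is None

    def test_fpeak_outside_range_rejected(self):
        f = np.linspace(0, 8, 64)
        with pytest.raises(DomainError):
            ct.fit_half_gaussian_sigma(curve(np.ones_like(f), f), 9.5)


class TestAverageFrequency:
    def test_flat_curve_mean_is_half_nyquist(self):
        assert ct.average_frequency(curve(np.ones(257))) == pytest.approx(4.0)

    def test_single_bin_spike(self):
        f = np.linspace(0, 8, 2561)
        v = np.zeros_like(f)
        v[np.argmin(np.abs(f - 3.2))] = 1.0
        assert ct.average_frequency(curve(v, f)) == pytest.approx(3.2, abs=1e-9)

    def test_rayleigh_closed_form(self):
        # f * exp(-f^2/2): first moment sqrt(pi/2) over unit zeroth moment
        f = np.linspace(0, 8, 4097)
        nps = curve(three_param_model(f, 1.0, 0.0, 1.0), f)
        assert ct.average_frequency(nps) == pytest.approx(np.sqrt(np.pi / 2),
                                                          abs=1e-4)

    def test_zero_area_rejected(self):
        with pytest.raises(DegenerateInputError):
            ct.average_frequency(curve(np.zeros(64)))


class TestRSAD:
    def test_identity_and_uniform_scale(self, body_curve):
        assert ct.rsad(body_curve, body_curve) == 0.0
        scaled = body_curve.with_values(1.1 * body_curve.values)
        assert ct.rsad(scaled, body_curve) == pytest.approx(10.0, abs=1e-9)

    def test_split_scale_case(self):
        # 1.2x on bins holding half the total, 0.8x on the rest -> 20%
        v = np.ones(64)
        param = np.where(np.arange(64) < 32, 1.2, 0.8)
        measured = curve(v)
        assert ct.rsad(curve(param), measured) == pytest.approx(20.0, abs=1e-9)
        # independent element-by-element oracle
        oracle = 100 * np.sum(np.abs(param - v)) / np.sum(v)
        assert ct.rsad(curve(param), measured) == pytest.approx(oracle)

    def test_scale_homogeneity_degree_zero(self, body_curve):
        other = body_curve.with_values(body_curve.values * 1.3 + 0.01)
        r1 = ct.rsad(other, body_curve)
        r2 = ct.rsad(other.with_values(5.0 * other.values),
                     body_curve.with_values(5.0 * body_curve.values))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_grid_mismatch_rejected(self, body_curve):
        f = np.linspace(0, 8, 33)
        with pytest.raises(AlignmentError):
            ct.rsad(curve(np.ones_like(f), f), body_curve)


class TestCharacterize:
    def test_body_reference_round_trip(self, body_curve):
        d = ct.characterize(body_curve)
        assert d.f_peak == pytest.approx(BODY[0], abs=0.02)
        assert d.sigma == pytest.approx(BODY[1], abs=0.02)

    def test_lung_reference_round_trip(self, lung_curve):
        d = ct.characterize(lung_curve)
        assert d.f_peak == pytest.approx(LUNG[0], abs=0.02)
        assert d.sigma == pytest.approx(LUNG[1], abs=0.02)

    def test_ramp_only_curve_flagged_no_downslope(self):
        f = np.linspace(0, 8, 257)
        d = ct.characterize(curve(f.copy(), f))
        assert not d.has_downslope
        assert d.sigma is None

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 250.0])
    def test_scale_invariance(self, body_curve, scale):
        base = ct.characterize(body_curve)
        scaled = ct.characterize(
            body_curve.with_values(scale * body_curve.values, normalized=False))
        assert scaled.f_peak == pytest.approx(base.f_peak, abs=1e-9)
        assert scaled.sigma == pytest.approx(base.sigma, abs=1e-9)
        assert scaled.f_av == pytest.approx(base.f_av, abs=1e-9)
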
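# cttexture

Tools for modeling, synthesizing, and psychophysically probing **CT noise
texture**.

In CT imaging the *shape* of the noise power spectrum (NPS) — not just the
noise magnitude — determines how images look and how well low-contrast
lesions can be found. Iterative and deep-learning reconstructions shift the
NPS toward lower frequencies, producing the "plasticky" or "blotchy" look
radiologists notice. This package implements a compact, quantitative
toolkit for studying that phenomenon, aimed at medical physicists and image
perception researchers:

- **Parametric NPS models.** The radial 1-D NPS (frequencies in lp/cm) is
  fit with the six-parameter form
  `NPS(f) = a·f^b·exp(−|f^c − α|^d / 2β²)` or its reduction with
  `(b, c, d) = (1, 1, 2)`, a ramp times a Gaussian whose peak frequency is
  analytic: `f_peak = (α + √(α² + 4β²)) / 2`.
- **A two-parameter shape descriptor.** Any NPS is summarized by
  `f_peak` (upslope) and `σ`, the width of a half-Gaussian
  `a′·exp(−(f − f_peak)²/2σ²)` fitted through the downslope
  (`f ≥ f_peak`); the average frequency `f_av` is also reported. Curves
  still rising at Nyquist are flagged as having no downslope.
- **NPS estimation.** From stacks of noise-only slices: mean-subtracted
  central-ROI periodograms, slice-averaged and radially binned, with exact
  Parseval bookkeeping (HU²·cm²).
- **Colored-noise synthesis.** A target `(f_peak, σ)` is converted to model
  parameters, revolved into a radially symmetric 2-D NPS, and applied to
  white Gaussian noise in the Fourier domain, yielding seeded, reproducible
  noise patches with a prescribed spectrum.
- **Ideal-observer statistics.** The log-likelihood ratio for deciding
  which of two stationary Gaussian textures a patch came from, computed in
  the Fourier domain (`(1/M)Σ(1/S₁ − 1/S₂)|ĝ − μ̂|²`, with optional
  regularization) and validated against a dense spatial-domain oracle. The
  texture contrast `C_texture = ∫|NPS2D,1 − NPS2D,2|` quantifies how
  different two spectra are.
- **Simulated 2AFC staircase experiments.** Three patches per trial
  (reference, match, odd one out); a 3-down-1-up staircase with 15% steps,
  stopped after 12 reversals, estimates the ~80%-correct threshold as the
  geometric mean of the last 8 reversal offsets; 6 repetitions per
  direction (first discarded) give per-direction detectability thresholds
  along 8 canonical directions in `(f_peak, σ)` space.
- **Threshold-ellipse analysis.** A least-squares conic, constrained to an
  ellipse, fitted through the per-direction thresholds; center, axes,
  major-axis angle, per-parameter chord thresholds, and iso-`f_av` /
  iso-`f_peak` curves.

## Worked example

```python
import cttexture as ct

# Characterize the bundled body-kernel reference shape
alpha, beta = ct.solve_model_params(1.89, 1.28)   # model params for targets
curve = ct.model_nps1d(alpha, beta)               # unit-area NPS, 0-8 lp/cm
desc = ct.characterize(curve)
print(f"f_peak={desc.f_peak:.3f}  sigma={desc.sigma:.3f}  f_av={desc.f_av:.3f}")
# f_peak=1.891  sigma=1.280  f_av=2.209

# Synthesize a noise stack with that spectrum and estimate its NPS back
stack = ct.generate_phantom_stack(curve, n_slices=200, size=128, seed=42)
est = ct.normalize_unit_area(ct.estimate_nps1d(stack, roi_size=128))
target = est.with_values(curve.interpolate(est.frequencies))
print(f"round-trip RSAD = {ct.rsad(ct.normalize_unit_area(target), est):.2f}%")
# round-trip RSAD = 1.15%

# Fit the detectability-threshold ellipse through the bundled
# per-direction thresholds for the body reference
ell = ct.fit_threshold_ellipse(ct.threshold_points("body"))
print(f"center=({ell.center[0]:.2f}, {ell.center[1]:.2f})  "
      f"angle={ell.angle_deg:.0f} deg  "
      f"f_peak threshold={ct.ellipse_fpeak_threshold(ell, 1.28):.2f} lp/cm")
# center=(1.86, 1.30)  angle=143 deg  f_peak threshold=0.19 lp/cm
```

The ellipse center sits at the reference NPS shape, its major axis runs at
143° to the `f_peak` axis (changes that trade `f_peak` against `σ` in
opposite directions are hardest to see), and a change of about 0.2 lp/cm in
peak frequency alone is at the edge of detectability for the body texture.

A `cttexture` command-line interface wraps the same functionality
(`cttexture nps estimate/fit/describe`, `cttexture synth patch/stack`,
`cttexture contrast`, `cttexture staircase`, `cttexture experiment`,
`cttexture ellipse`); run any subcommand with `--help`.

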
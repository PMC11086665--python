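# Methods

## The NPS models and the (f_peak, σ) descriptor

A CT noise power spectrum along the radial frequency axis `f` (lp/cm ≡
cycles/cm) typically rises as a ramp at low frequencies and rolls off at
high frequencies where the reconstruction kernel apodizes. The package
models this with

- the six-parameter form `a·f^b·exp(−|f^c − α|^d / 2β²)`, and
- the reduced form with `(b, c, d) = (1, 1, 2)`:
  `a·f·exp(−(f − α)² / 2β²)`.

The reduced model's maximum is analytic, `f_peak = (α + √(α² + 4β²))/2`,
which both anchors the model-independent descriptor and lets the generator
eliminate one parameter in closed form.

The descriptor itself is model-agnostic: `f_peak` is the location of the
maximum of the curve after low-pass filtering (see below), and `σ` is the
width of the half-Gaussian `a′·exp(−(f − f_peak)²/2σ²)` least-squares
fitted to all samples with `f ≥ f_peak`. Ramp-only spectra — peak in the
last two frequency bins, or a non-decreasing tail — have no downslope and
get `σ = None` rather than a number. The average frequency `f_av` is the
normalized first moment `∫f·NPS df / ∫NPS df` by the trapezoid rule; no
other definition is in use here. Mismatch between a parameterized and a
measured curve is reported as the RSAD, `100·Σ|param − measured| / Σ
measured`: a ratio of sums rather than a sum of per-bin ratios, because
per-bin ratios diverge wherever the measured curve approaches zero and a
single percentage per curve is wanted.

Because only the NPS *shape* matters for texture, all modeled curves are
normalized to unit trapezoidal area, and `characterize()` is
scale-invariant by construction.

### Peak finding

Measured spectra carry narrow spurious peaks. The peak is therefore located
on the curve filtered with a zero-phase 4th-order Butterworth low-pass
whose cutoff sits at 4% of the full bandwidth of the frequency-axis
sampling (i.e. `Wn = 0.04` in scipy's normalized units). On the default
1025-sample model grid this leaves genuine lobes (widths ~1 lp/cm)
untouched while attenuating single-bin spikes by roughly an order of
magnitude. The pipeline runs the peak search and the σ fit on the fitted
three-parameter curve by default (`peak_source="fitted"`); a
`peak_source="raw"` switch uses the normalized input curve directly, for
spectra the model represents poorly.

### Fitting determinism

Nonlinear fits use a fixed multi-start grid (α ∈ {−2, 0, 2, 4}, β ∈ {0.5,
1, 2, 4} lp/cm, amplitude from a linear projection), best residual wins,
ties broken by smallest α; there are no random restarts. The six-parameter
fit is initialized at the reduced solution embedded at `(b, c, d) = (1, 1,
2)` and falls back to it if the optimizer does not improve the residual, so
its r² is never below the nested model's. r² is `1 − SS_res/SS_tot` about
the curve mean; negative values are allowed (poor fits), and a perfectly
flat curve (zero SS_tot) reports r² = 0 with finite parameters rather than
an error.

## NPS estimation

Estimation follows the standard water-phantom protocol: the central
128×128-pixel ROI of each slice (≥100 slices by default; both
configurable) is mean-subtracted, its 2-D periodogram `|FFT|²·Δx²/N²` is
averaged over slices, and the average is radially binned at the FFT's
native frequency step, with empty bins (none at these sizes) filled by
linear interpolation. The scaling makes Parseval exact: the 2-D integral of
the unnormalized spectrum equals the mean per-slice ROI variance, so units
are HU²·cm². Mean subtraction is the simplest detrending variant; the
synthetic fixtures are stationary, so higher-order detrending would only
complicate the Parseval bookkeeping.

## Synthesis

`solve_model_params(f_peak, σ)` inverts the descriptor: the peak constraint
gives `β² = f_peak(f_peak − α)` exactly, and a Brent root search over α
matches the measured downslope width of the generated curve to the target
σ (residual tolerance 1e−6 lp/cm). The σ measurement inside the solver
uses the same half-Gaussian fit as `characterize`, which is what makes the
generator/characterizer round trip close to within ~0.001 lp/cm. Two
infeasibility regimes are detected and raised: targets narrower than the
sampling grid can resolve, and targets wider than the model can produce —
the reduced model's downslope width saturates near `1.64·f_peak` as
α → −∞, so, e.g., (f_peak = 1, σ = 5) has no solution.

The 1-D curve is revolved assuming radial symmetry: each 2-D frequency bin
takes the linearly interpolated 1-D value at its radius, with the DC bin
and the corner region beyond the 1-D Nyquist set to zero. Colored noise is
realized as `N = F⁻¹{√NPS2D · F{n}}` with `n` seeded unit white Gaussian
noise: filtering by the *square root* of the target spectrum is the
convention under which the realized power spectrum equals the target, and
it is the default; filtering by the spectrum itself (which squares the
realized shape) is available as `filter_convention="literal"` and is
covered by a test demonstrating the squaring. Patches are rescaled post
hoc to sample-exact mean and SD, which removes realization variance from
display windowing (level μ, width 10·SD) and from the observer's intensity
statistics. Per-slice seeds come from a counter-based
`SeedSequence([master, i])` scheme, so any slice is reproducible
independently of generation order.

Default pixel spacing is 0.0625 cm (Nyquist 8 lp/cm), wide enough to cover
the lung-kernel spectrum's support; it is a free parameter everywhere.

## Observers

Texture classes are stationary Gaussian fields sharing a mean, so their
covariances are circulant and diagonalize in the Fourier basis into
per-bin spectra `S₁, S₂`. The ideal-observer log-likelihood ratio reduces
to `(1/M)Σ_k (1/S₁[k] − 1/S₂[k])·|ĝ[k] − μ̂[k]|²`; `llr_fourier`
implements this with optional Tikhonov-style regularization (`S + ε²`,
default ε² = 10⁻⁶ × the maximum spectral value at decision time) and
excludes the DC bin by default — both hypotheses share the mean, so it
carries no texture information, and synthesized patches have exact sample
mean anyway. `llr_spatial` is the dense oracle: it materializes `Σᵢ =
(1/M)F*·diag(Sᵢ)·F`, inverts explicitly, and is used only on small grids
to validate the Fourier route (they agree to 1e−8 relative on valid
spectra, i.e. those with the real-field symmetry `S[k] = S[−k]`).

For 2AFC decisions the ideal observer scores both alternatives with the
same LLR and picks the one favoring the reference hypothesis; the
log-determinant terms cancel between alternatives, and ties go to the
first. The psychometric observer instead answers correctly with
probability `ψ(x) = 1 − 0.5·exp(−(x/τ)^k)` (2AFC Weibull, guess rate 0.5,
default slope k = 3.5 — a realistic steepness for texture discrimination —
threshold scale τ configurable), where the stimulus `x` maps from the
trial's parameter offset via a pluggable `stimulus_map` (default:
Euclidean magnitude of `(Δf_peak, Δσ)`).

The texture contrast `C_texture = Σ|NPS2D,1 − NPS2D,2|·Δf²` multiplies the
bare bin sum by the 2-D bin area so the value approximates the continuous
integral and is stable under grid refinement; the bare-sum convention is a
flag. Absolute published C_texture values depend on an unstated grid and
HU normalization, so they are treated as order-of-magnitude context, not
targets.

## Staircase experiments

The staircase is a transformed up-down rule: after 3 consecutive correct
responses the offset magnitude shrinks (counter resets on every down-step
and every error), after any error it grows; steps are 15% of the current
value (down ×0.85, up ×1.15). A reversal is logged at the trial where the
step direction changes, carrying the offset presented on that trial (the
trajectory extremum). A run stops at 12 reversals (or a 200-trial guard,
flagged); its estimate is the geometric mean of the offsets at the last 8
reversal trials. An alternative aggregation over all trials from the first
used reversal onward is available (`reversal_aggregation="trials_between"`).
Six repetitions per direction are run; the first is practice and is
discarded, and the arithmetic mean of the last five estimates is the
direction's threshold, reported as a magnitude and as `(Δf_peak, Δσ) =
threshold · direction`.

Two details worth knowing:

- With the literal multiplicative steps the zero-drift point of the
  procedure satisfies `p³ = ln 1.15 / (ln 1.15 − ln 0.85)`, i.e. p* ≈
  0.773 rather than the textbook `0.5^{1/3} ≈ 0.794` of log-symmetric
  steps; simulations here measure a mean ψ at the returned estimates of
  ≈ 0.76. The log-symmetric variant (down-step ÷1.15) is available as
  `StaircaseConfig(step_down_mode="reciprocal")`.
- For diagonal directions the staircase variable is the scalar magnitude
  along the unit direction vector, so the `Δf_peak : Δσ` ratio stays
  locked within a direction.

Offsets that would drive a parameter negative are capped at the feasible
maximum; persistent capping (≥5 ceiling hits) flags the run `no_threshold`
— the regime where a real observer would have needed a larger difference
than the parameter space allows. Start offsets default to well above
threshold (8× the nominal threshold in the convergence studies). All
randomness flows from explicit seeds; an experiment is bit-reproducible
from its master seed.

Psychometric-style observers run *abstractly* (Bernoulli draws from ψ, no
patches synthesized), which makes a full 8-direction experiment run in
milliseconds; ideal observers get fully synthesized trials.

## Threshold-ellipse analysis

The ellipse is fitted to the ≥5 absolute threshold points by algebraic
least squares on the conic `Ax² + Bxy + Cy² + Dx + Ey + F = 0`. The
default normalization is Bookstein's `A² + B²/2 + C² = 1`, which is
invariant under rigid motions, so the fitted center and angle are exactly
equivariant under translation and rotation of the points; the fit raises a
non-elliptical error (carrying the conic) if the best conic is a
hyperbola or parabola. The Fitzgibbon/Halir-Flusser ellipse-specific
constraint `4AC − B² = 1`, which cannot return a non-ellipse, is available
as `method="fitzgibbon"` for noisy data; on the bundled threshold tables
the two differ visibly (the generic-conic fit reproduces the published
geometry more closely, which is why it is the default). Angles are
measured counterclockwise from the +f_peak axis with equal axis scaling in
(lp/cm, lp/cm) — plotting with unequal aspect changes apparent angles,
not these numbers.

The per-parameter `f_peak` threshold is half the horizontal chord of the
ellipse at the reference σ (the quadratic in `x` obtained by fixing `y`);
averaging the two pure-f_peak directions is an alternative reading, and
both are accessible. Iso-`f_av` curves solve, at each `f_peak` of a span,
for the σ whose generated model curve keeps the reference `f_av`
(bracketed Brent, tolerance 1e−4 lp/cm); the curve only exists for
`f_peak` below the target `f_av` — a spike at `f_peak` has `f_av = f_peak`,
and widening the downslope only raises `f_av` — so out-of-range span
values truncate the curve with a flag.

## What the synthetic generator does and does not emulate

The phantom-stack generator produces stationary, radially symmetric,
Gaussian colored noise with exactly the prescribed spectrum — the ideal
form of a homogeneous water-phantom acquisition. It does not emulate
nonstationarity across the field of view, beam hardening or scatter
structure, through-plane correlation (slices are independent),
non-Gaussian marginals of nonlinear reconstructions, or anatomical
background. Tests passing on these fixtures therefore validate the
numerics (estimation scaling, round trips, observer mathematics,
staircase logic), not robustness to real-scanner deviations from
stationarity or Gaussianity.

## Problem sizes

Default study sizes keep everything desk-scale: 1025-sample model curves
on 0–8 lp/cm, 128×128 ROIs and patches (64×64 for ideal-observer Monte
Carlo), 200-slice stacks for estimation round trips (500 for the isotropy
check), 500 staircases for convergence statistics, and 8 directions × 6
repetitions for closed-loop experiments. The dense spatial LLR oracle runs
on grids up to 16×16, where its M²-sized matrices are still trivial.

## Known limitations

- The reduced model cannot represent downslopes wider than ≈1.64·f_peak;
  the generator raises rather than silently clipping.
- The σ fit is unweighted over the whole tail; very long, nearly flat
  tails can pull σ relative to a weighted variant.
- The descriptor's `f_peak` is bin-quantized by the sampling grid
  (±0.004 lp/cm at the default resolution).
- `llr_spatial` assumes (and does not verify) the real-field spectral
  symmetry; spectra built from radial curves satisfy it automatically.
- The staircase's literal multiplicative steps converge slightly below
  the nominal 79.4% point, as quantified above.
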
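# Methods

This note documents the models implemented in `dnamech`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the problem was genuinely
open.

## Empirical force–extension model

The product form `F(x) = f1·(f2 + f3)` — logistic sigmoid × (plateau
line + hyperbola) — is an *empirical* description of a four-regime
dsDNA stretch curve, not a statistical-mechanics model. Its virtues are
that each parameter tracks one physical feature (contour length,
compliance, overstretch cooperativity and stability, maximal length)
and that it is smooth and cheap to fit. Its pole at `x = P5` means the
model is only defined for extensions strictly below the hyperbola
asymptote; evaluation at or beyond `P5` raises an error rather than
returning a signed infinity.

Fitting is unweighted nonlinear least squares with Levenberg–Marquardt
(lmfit's `leastsq`, bounds enforced through its internal parameter
transform; at most 10 000 function evaluations; `ftol = xtol = 1e-14`
so noiseless round trips reach ≲1e-12 relative error). Bounds keep
`P2, P6 > 0` and confine `P5` to `(max x, 3·max x]` so the pole can
never enter the fitted data range, even when a user-supplied initial
guess puts it there. Curves are sorted by extension and duplicate
extensions averaged before any fit, which keeps interpolation and the
plateau-window heuristics well defined.

Automatic initialization: the plateau is identified as the flattest
stretch of the curve — on a uniform extension grid, the densest force
band, taken as the modal force-histogram bin between 30% and 100% of
the 95th-percentile force (with the band `[0.8, 1.0] ×` that percentile
as a sparse-data fallback). A top-quantile band alone misidentifies the
plateau on curves that continue deep into the asymptotic regime, where
the highest forces sit on the steep post-plateau rise. `P1` is the
extension at which force first exceeds half the plateau estimate; `P2`
comes from the 25%→75% rise width divided by `2·ln 3` (the exact
logistic relation); `P5 = 1.05·max x`; `P6` from the high-force excess
over the plateau line. During fitting `P1` is additionally confined to
the recorded extension range and `P2` to the data span, which prevents
the sigmoid from degenerating into a constant on curves the model only
approximates. On noiseless model-generated curves the initializer lands
within ~20% of the truth, well inside the optimizer's basin. Only stretch-direction curves
are fitted by the pipeline; relax curves can carry hysteresis that the
model does not describe.

The plateau-derived metrics use the line component only: height
`P3·25 + P4` at the conventional 25 μm reference extension, slope `P3`,
and cooperativity proxy `1/P3` (reported as `+inf` when the slope is
zero or negative).

## Wormlike chains

The WLC and eWLC interpolation formulas are implemented with extensions
and contour lengths in μm, persistence lengths in nm, forces in pN and
`kBT` in pN·nm (default 4.114 pN·nm, 25 °C — the AFM work was done at
25 °C and the trap temperature is taken to match; configurable
everywhere). The eWLC is implicit in `F`; it is solved per point by
Brent bracketing on `[0, 1e4]` pN followed by up to three Newton steps,
and every returned force satisfies the dimensionless equation to better
than 1e-10. For `z > Lc` the equation grows a spurious root on the
branch `1 − z/Lc + F/κ < 0`; the solver restricts the bracket to the
physical branch, where the residual is strictly monotone and the root
unique.

A genuine property of the model pair worth recording: the inextensible
limit eWLC → WLC converges like `(dF/dz)·F/κ`, which diverges towards
the WLC pole. At `κ = 1e9 pN` the two models still differ by ~3e-6 pN
at `z = 0.95·Lc` (for Lp = 50 nm); sub-1e-6 agreement over that full
range needs `κ ≳ 1e11 pN`. The test suite asserts the limit in the
regime where it holds.

Polymer fits select points inside a force window — `(0, 20]` pN by
default for dsDNA (the low-force regime where the eWLC is a faithful
description), `(0, 60]` pN for ssDNA comparisons — and require at least
10 in-window points. `Lc` is bounded above `max z` for the WLC (hard
pole) but may go below `max z` for the eWLC (enthalpic stretching).

For AFM-adsorbed chains, `Lp = ⟨R²⟩/(4·Lc)`. Applied to the published
sample means this gives 12.8 nm for ligand-treated DNA; for the control
sample the same arithmetic gives ≈12.2 nm, whereas 10.8 nm has been
reported from the underlying raw data — per-molecule versus pooled
averaging of `R²` changes the estimate, and raw traces are not
available to resolve which was used. Both estimators (`⟨R²⟩` and
`⟨R⟩²`) are therefore provided; the sample-level default is
mean-of-squares.

## Stiffness

The instantaneous apparent stiffness is `dF/dx` computed by central
divided differences on the measured, non-uniform extension grid
(one-sided at the endpoints), with no resampling — interpolation near
the plateau shoulder would bias the peak. Optional smoothing is
Savitzky–Golay (default window 21 points, order 3; the smoothing used
for the published stiffness figures is not specified, so this is a
declared choice, and a raw mode is provided). Peak extraction is the
windowed arg-max with ties broken towards smaller extension and a flag
when the maximum sits on the window edge (a boundary peak is not a
peak).

## Equilibrium binding

`ΔL(F)` is read out by subtracting control from treated extension at
matched forces. The readout interpolates extension on the strict
record-high envelope of the force trace, which is the monotone
pre-plateau segment even in the presence of 0.37 pN noise. The default
force grid is 0–20 pN at 1 pN steps; because measured curves rarely
reach exactly 0 pN, the default grid is clipped to the jointly covered
range (an explicitly supplied grid is strict and raises on any
uncovered point). Zero-force lengthening is obtained from the fitted
isotherm's intercept, not from data extrapolation.

The multi-site isotherm is fitted per concentration with all three
parameters floating: `Δx_eq ∈ (0, 2]` nm, footprint `n ∈ [1, 50]` bp,
and `K0` on a log10 scale in `[1e2, 1e9]` 1/M (log parameterization
conditions the problem; affinities are scale quantities). `Nbp` is
fixed at 48 502 for λ-phage DNA. Diagnostics flag all-zero curves and
parameters pinned at bounds instead of failing.

The concentration dependence of ΔL at fixed force is fitted with
`A_f(1−e^(−C/c_f)) + A_s(1−e^(−C/c_s))`; the characteristic
concentrations are the fitted decay constants (the "1/e of ΔL_max"
phrasing literally marks a 1−1/e saturation point; the decay-constant
reading is used and the ordering `c_fast ≤ c_slow` is enforced by
sorting, with a flag when the two constants differ by less than 2×).

## Perturbation kinetics

Segmentation uses explicit phase labels when present (windows are label
runs), otherwise force-step detection: a change above 2 pN within a
100 ms lookback marks a transition, whose onset is then refined by
backtracking to where the force first left its pre-step baseline by
more than 0.5 pN. Every window starts `settle` seconds after its
transition — 50 ms for force jumps, 300 ms for concentration jumps by
default, configurable because the correct value is the instrument's
stabilization time. Only post-settle data enter rate fits, because the
elastic response during the ramp is not reaction kinetics.

Mono-exponential fits `L(t) = L∞ − ΔL·e^(−kt)` are initialized from the
mean of the last 10% of points (asymptote) and a log-linear fit of the
residual decay (rate). Results are flagged unreliable — and excluded
from downstream Bell fits — when the optimizer fails, when the window
spans fewer than 0.2 relaxation times, or when the amplitude is within
3 residual SDs of zero.

Bell fits require ≥3 rate points spanning ≥15 pN; `Δx` is sign-free
(dissociation rates can slow under load). Points carrying standard
errors are weighted by `1/se`, which prevents the fastest, noisiest
rates from dominating the unweighted residual. The linear decomposition
`k0 = k_on·C + k_off` is ordinary least squares — exact for two
concentrations; negative estimates below 1e-9 are clipped to zero and
materially negative ones flagged rather than hidden. Force-jump and
concentration-jump experiments are analysed by the same machinery but
reported side by side; no attempt is made to reconcile the two, which
probe the reaction along different perturbation pathways.

## Synthetic data

All generators are pure functions of (parameters, seed) built on
`numpy.random.default_rng`; there is no hidden global state.

* **FEC generators** add i.i.d. Gaussian force noise (SD 0.37 pN by
  default, the typical measured force noise of the emulated instrument
  class) to the empirical model, to a WLC/eWLC curve, or to a piecewise
  mechanistic curve (dsDNA eWLC up to the plateau force, linear plateau,
  ssDNA eWLC branch joined at its crossing with the plateau line —
  continuous by construction, with inconsistent branch parameters
  rejected). Defaults: dsDNA Lc 16.37 μm / Lp 50 nm / κ 1200 pN, 65 pN
  plateau, ssDNA Lc 27 μm / Lp 1 nm / κ 800 pN; grid 10–31 μm at 10 nm.
* **Kinetic traces** emulate the jump protocols: ~30 ms force ramps in
  5 pN steps (concentration transfers ~250 ms), 2 kHz length sampling,
  ~0.5 μm of length change per force step of which 90% is instantaneous
  elastic response — so the kinetically relaxing amplitude is ~50 nm
  against 5 nm length noise, matching the regime in which such
  experiments are actually analysable. Phase durations adapt to
  5/k_obs (minimum 0.25 s).
* **AFM samples** draw contour lengths from a truncated normal and
  end-to-end distances around `sqrt(4·Lp_target·Lc)` with 20% relative
  jitter, clipped below the contour length.

What the generators deliberately do **not** reproduce: force-curve
hysteresis (stretch ≠ relax), sequence-dependent overstretching, strand
unpeeling and melting-bubble physics, drift and low-frequency
instrument noise, manual-tracing subjectivity in AFM, and any
correlation structure in the noise. Passing recovery tests on this
synthetic data therefore demonstrates the *estimators* are correct and
well conditioned at realistic noise levels — not that real curves obey
the models.

## Problem sizes

The test suite and the acceptance script use: 200–2000-point FECs;
50 random parameter draws for the empirical round-trip; 100 replicates
for isotherm K0 recovery (20 force points, 0.05 μm ΔL noise); 50 seeded
replicates (500 points each) for the ssDNA eWLC contour-length
recovery; and 50 seeds × 2 concentrations × 8 force steps for the
end-to-end kinetics pipeline. These sizes give stable medians while
keeping a full run in tens of seconds on one CPU.

## Known limitations

* The empirical model's parameters are correlated (notably `P5`/`P6`
  when the data stop far from the pole); standard errors from the
  covariance matrix should be read with that in mind.
* `length_at_force` assumes the pre-plateau force envelope is
  informative; curves that begin above the requested force cannot be
  read out and raise rather than extrapolate.
* The isotherm is a single-species, non-cooperative lattice model; a
  ligand with multiple binding modes will show effective,
  concentration-dependent parameters rather than constants.
* Step detection assumes roughly uniform sampling when converting the
  100 ms lookback to samples.
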
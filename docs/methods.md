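# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `pursuitkit`.

## Target motions

All stimuli are periodic 2-D motions with period T = 4.5 s (fundamental
f₀ = 1/T ≈ 0.222 Hz). Coordinates are degrees of visual angle, x rightward
and y upward positive; direction is measured counter-clockwise from the
rightward horizontal.

**Sum of sines (SS).** Each axis is `A₁ sin(2πf₀t + φ₁) + A₂ sin(2πkf₀t +
φ₂)` with harmonic order k ∈ {2, 3}. The stock library ships five such
paths whose coefficients were chosen once to satisfy the stimulus
constraints — peak 2-D speed between 30 and 40 °/s, excursion within a
±15° display window, one 2nd- or 3rd-harmonic per axis, and path 3 pairing
a 3rd x-harmonic with a 2nd y-harmonic. The exact published coefficients
are not recoverable, so these are constraint-satisfying stand-ins and every
coefficient is user-configurable (`save_specs` / `load_specs`).

**Constant speed (CS).** The SS path re-traversed at the constant speed
L/T, where L is the one-period arc length. Implementation: speed is
tabulated on a 4096-sample grid, cumulative arc length is integrated by the
trapezoid rule, and the inverse map t(s) is built with monotone PCHIP
interpolation. Velocity and acceleration then follow from the chain rule,
so the speed equals L/T by construction and the warp accuracy only affects
timing; an independent finite-difference oracle confirms speed constancy to
well under 0.1%. Paths whose SS speed approaches zero (cusps) are warned
about: the CS trajectory is still defined but its acceleration is unbounded
at the cusp.

**Mixed.** The x velocity of one profile combined with the y velocity of
the other. Because each position component is exactly the integral of its
own velocity component, the mixed trajectory is the exact component splice
of its sources — it is periodic with no closure error, so no numerical
integration is needed.

## Pursuit models

State is eye velocity **v**ₑ (deg/s); the eye is at rest before motion
onset (zero history for t < 0) and targets are evaluable at any real time.

**Image-velocity model.** Per axis i,

    dv_e,i/dt = a [ g_i v_t,i(t − τ_t) − v_e,i(t − τ_e) ]

a first-order lag (rate a, per-axis gain g) on retinal image velocity with
separate target and eye delays. Its transfer function is
`H(ω) = g a e^{−iωτ_t} / (iω + a e^{−iωτ_e})`.

**Predictive model.** The same structure with a single common delay τ plus
a predictive drive built from target acceleration: the acceleration is
decomposed into tangential (rate of change of speed) and normal
(proportional to curvature) components, each carried as a vector along its
unit vector, and low-pass filtered with rate b (`dâ/dt = b(a_chan − â)`).
The channels enter with weights c₁ (normal) and c₂ (tangential), in
seconds, so c·â has velocity units:

    dv_e,i/dt = a [ g_i v_t,i + c₁ â_n,i + c₂ â_t,i − v_e,i ](t − τ)

The channels are vectorized *before* filtering; with c₁ = c₂ = c they
reassemble the componentwise filtered acceleration exactly, making the
model linear per axis with transfer function
`H(ω) = a (g + c iω b/(b+iω)) e^{−iωτ} / (iω + a e^{−iωτ})`. (Filtering
the scalar channels and re-vectorizing afterwards would not commute with
the rotation of the velocity frame and would break this identity.)
Because the filter input is periodic, the steady-state filtered signal is
computed spectrally — each Fourier component scaled by b/(b + iω) — which
is the exact steady-state solution of the filter ODE.

**Polar model.** Eye speed and direction as controlled variables:
`dv/dt = a (v̂ₑ·v_p − v(t−τ))` with v_p the gain-scaled, delay-shifted
predicted target velocity (including the predictive-acceleration terms),
and direction driven by the shortest-arc error θ_t − θₑ at rate d
(standard variant), or with the *normal acceleration* v·dθ/dt proportional
to that error (directional-error variant). Eye speed at or below the
0.5 °/s floor freezes the direction dynamics. The model is nonlinear; its
solution is cross-checked against a brute-force fixed-step Euler
integration at dt = 10⁻⁴ s.

### Integration

Delay differential equations are integrated by the **method of steps**:
within successive windows of one delay the delayed state is known from the
stored dense solution, so each window is an ordinary ODE solved with
adaptive RK45 (rtol 1e-8, cubic dense output; scipy's `solve_ivp`).
Simulated linear responses match their closed-form transfer functions to
~1e-8 relative.

For model fitting, where the linear models are simulated thousands of
times, a fixed-step classical RK4 fast path is used instead: the exogenous
input (everything except the delayed eye-velocity feedback) is tabulated on
a half-step grid up front, the state delay is an integer number of ~2 ms
steps, and delayed half-step values come from cubic Hermite interpolation
of the stored solution. This path agrees with the adaptive integrator to
better than 1e-5 relative at roughly a tenth of the cost, far below the
fit tolerances.

## Synthetic experiments

The generator emulates the study design — 5 paths × 4 motion profiles ×
10 trials per condition, 250 Hz position traces of 5.7 s (1.25 periods) —
with the predictive model as ground truth (per-subject parameter rows from
the published best-fit table; per-profile overrides available, e.g.
predictive weight 0.39/0.29/0.21 for SS/mixed/CS).

* **Velocity noise**: Gaussian, low-pass filtered at 25 Hz (2nd-order
  Butterworth, zero phase) and rescaled to SD 1 °/s. Filtering keeps the
  differentiated 250 Hz position noise realistic; raw white noise would
  dominate the derivative.
* **Binocular averaging**: two eyes with independent noise, averaged
  (default on).
* **Catch-up saccades**: whenever the position error exceeds 1.5°, a
  minimum-jerk position step of the full error over 30 ms, followed by one
  saccade-duration refractory period. Saccades are injected once, on the
  binocular-averaged trace — they are conjugate movements, and averaging
  independently-timed per-eye saccades would instead produce half-amplitude
  steps slow enough to evade the saccade detector. The generator is deliberately
  simple — its job is to exercise saccade detection and desaccading, not
  to model saccade kinematics. Note that with tracking gain below one the
  sustained retinal-velocity error (6–10 °/s in CS conditions) drives 3–5
  catch-up saccades per second, so intact CS trials legitimately have
  30–40% of samples inside detected saccade intervals.

What the generator does **not** emulate: blinks, fixational eye movements,
pupil artefacts, cognitive anticipation of the display border, and any
time-variation of the predictive gain within a trial. Passing tests
therefore demonstrate the correctness and calibration of the analysis
chain under the model's own assumptions, not the validity of the model for
real eyes.

## Preprocessing

Position → velocity: double-sided exponential smoothing (4 ms time
constant; a first-order exponential filter run forward then backward, zero
net phase, edge-held initial state), then centered-difference
differentiation. Saccade detection flags samples whose speed deviates from
a 100 ms local median by >50 °/s or whose acceleration exceeds 1000 °/s²,
dilates flags by a 12 ms guard margin per side and merges overlapping
runs; these thresholds are stand-ins for a criterion published elsewhere
and all are exposed as arguments. Flagged intervals are replaced by a
cubic spline through 20 flanking clean samples per side. Trials with more
than 50% of samples interpolated are rejected (a stand-in for the study's
blink/lost-pursuit rejection; the threshold sits above the ~40%
interpolation of intact constant-speed trials — see above). Retained
trials are averaged pointwise with their standard error.

## Frequency analysis

The steady-state window [1.0, 5.5) s spans exactly one period, so after
resampling to 512 points (cubic interpolation; linear available) every
target harmonic falls exactly on an FFT bin of spacing 1/4.5 Hz and no
taper is needed. Gain and phase are the complex ratio of eye to target
Fourier coefficients, phase in degrees with lead positive, reported both
wrapped to (−180°, 180°] and unwrapped. Across-subject phase statistics
use the circular mean, circular SD √(−2 ln R̄), and the Rayleigh test with
the standard finite-n corrected p-value (cross-checked against an
independent implementation and a 10⁵-draw Monte-Carlo null).

## Model fitting

Fits minimize the summed squared velocity error over [1.0, 5.5] s
(pursuit onset excluded) with Nelder–Mead (coefficients 1, 2, 0.5, 0.5;
stop at simplex size 1e-5 or 2000 iterations), multi-restart with starts
jittered ±30% around mid-range defaults, and quadratic penalties keeping
parameters inside physical boxes (rates positive, delays in [0, 0.3] s,
gains in (0, 1.5]). VNAF = 100·Σ(data−model)²/Σ(data−mean)², pooled over
axes and also per axis; normalization is about the data mean (an
about-zero variant is a flag).

Protocols: **P1** fits the image-velocity model per condition and axis
(free a, g, τ_t, τ_e); **P2** fits the predictive model to all conditions
per subject with the delay fixed at 80 ms (free a, b, c₁, c₂, g_x, g_y;
the delay can be freed, exposing the known delay/filter-rate trade-off);
**P3** fixes a, b, τ at the P2 estimates and fits g_x, g_y, c₁, c₂ per
condition. Because the predictive model is linear in those four
parameters, P3 objectives are evaluated from four precomputed
unit-coefficient basis simulations per condition — the same objective at a
fraction of the cost.

Identifiability caveat: a constant-speed condition has (by construction)
near-zero tangential target acceleration, so the tangential weight c₂ is
unidentifiable from CS data alone; its estimate stays near the start
point. Recovery tests therefore either include speed-modulated conditions
or score c₁ for CS.

## Interaction analysis

For a fixed profile on one axis, same-axis responses are compared between
the two conditions differing only in the other axis's profile. Gains are
matched first by least-squares regression **through the origin** (an
intercept would absorb DC differences the analysis wants to keep); the
scaled difference traces are t-tested pointwise across subjects (two-sided,
uncorrected, at α = 0.01 and 0.001, matching how such fractions are
conventionally reported; a permutation-based family-wise option exists but
is off by default), and characterized by their amplitude spectrum on the
512-point grid.

## Problem sizes

The test suite and `scripts/acceptance.py` run the fitting analyses on
scaled-down experiments chosen as the smallest designs that keep every
parameter identifiable: two paths (2 and 5) with the SS and CS profiles
(plus both mixed profiles for the condition-dependence analysis), one
synthetic subject, 10 trials per condition at the default noise for noisy
recovery, and single-restart P2 fits from the mid-range default start.
Closed-form, constant-speed and frequency-pipeline checks run at full
resolution.

## Known limitations

* The published paths' Fourier coefficients are unrecoverable; the stock
  library reproduces the printed constraints, not the figures.
* The saccade generator is kinematically crude (fixed duration, no main
  sequence beyond a scale, no undershoot).
* Nelder–Mead is a local optimizer; with the delay free, τ and b trade off
  and estimates become protocol-dependent (hence the fixed-delay default).
* The polar model's speed error uses the projection v̂ₑ·v_p; the
  speed-difference alternative |v_p| − v is available behind the
  `speed_error="difference"` switch but is not the default.
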
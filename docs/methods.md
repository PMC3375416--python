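# Methods

## Model

The package models the firing-rate deviation r(t) of a semicircular-canal
afferent (arbitrary units, linear in true rate) as the response of

    H(s) = K · s·(1 + τ_N·s) / ((1 + τ₁·s)·(1 + τ₂·s))

to head angular velocity ω(t) in deg/s. The denominator is the
torsion-pendulum description of cupula/endolymph mechanics (slow pole τ₁,
fast pole τ₂); the numerator `s` converts the velocity input to the
acceleration the cupula senses and the lead term (1 + τ_N·s) adds
sensitivity to the rate of cupular displacement. The adaptation operator
sometimes added to afferent models is deliberately omitted: perceptual
thresholds around 0.15–3 Hz do not constrain it, and leaving it out keeps
the model at three free parameters (K, τ₁, τ_N). τ₂ is fixed at 0.005 s, a
value derived from canal anatomy; it is far above the stimulus band and is
not identifiable from threshold data.

A stimulus is taken to be discriminable (the 75 %-correct operating point
of the 2AFC task) when the peak of |r(t)| reaches the afferent noise
level. The noise level is fixed at 1: it trades off exactly against K, so
only their ratio is identifiable. By linearity the velocity threshold of a
profile needs no iterative search:

    threshold = noise_level · v_peak / max_t |(h ∗ v)(t)|

An equivalent bisection search on the stimulus amplitude is kept in the
test suite as an independent oracle and agrees to 1e-6.

Assumptions inherited from this construction: the afferent stage is linear
and time-invariant; each trial starts from resting discharge (zero initial
conditions — inter-trial carry-over is not modelled, justified by the ≥2 s
standstill between stimuli near threshold level); a single noise level
serves all frequencies; central processing (velocity storage, ~16 s time
constant) does not shape thresholds — the fitted τ₁ below 1 s is consistent
with that exclusion.

## Stimuli

Stimuli are one period T of an acceleration waveform whose second half is
the negative mirror of the first, so velocity rises from zero to a peak and
returns to zero. Three acceleration shapes are generated in closed form —
triangular (peak at T/4), sinusoidal (A·sin 2πt/T), trapezoidal (linear
rise over dt = T/10, plateau, linear fall) — with velocity obtained from
the exact integral and scaled so max v equals the commanded peak velocity.
The closed forms give peak accelerations A = 4v/T, πv/T and v/(0.4T)
respectively: clearly distinct acceleration traces with nearly identical
velocity envelopes, which is what makes the shape comparison informative.
The triangular peak position and the sharp (unsmoothed) corners are
modelling choices; the default 1 kHz sample rate matches the rate at which
platform motion is typically recorded and is configurable.

## Numerics

- H is biproper, so it is discretized with the bilinear (trapezoidal)
  transform at the profile's sample rate and run as an IIR filter with zero
  initial state. Halving the time step changes peak responses by <0.5 % for
  every study condition (tested), and long-sinusoid steady-state amplitudes
  match |H(i2πf)| to 1 % up to 3 Hz.
- The input is zero-padded for 5·τ₁ after the stimulus so slow-pole
  transients cannot hide the global peak; the response peak location is
  otherwise unconstrained.
- Fitting minimises the sum of squared threshold errors with
  `scipy.optimize.least_squares` over log(K, τ₁, τ_N), which enforces
  positivity without bounds and equalises step scales. A deterministic
  5-start multistart (fixed ±0.7/±1.4 log perturbations of the starting
  point) guards against local minima; the best start is returned and a
  fitted τ_N below 1e-9 s is reported as the boundary value 0.
- Residuals are computed in linear deg/s by default. The printed SSE of the
  reference fit is consistent with linear residuals, but since thresholds
  are log-normally distributed a log-space objective is retained as an
  option (`objective_space="log"`), as is optional 1/SEM² weighting.
  Default: linear, unweighted.
- The starting point (τ₁ = 4 s, τ_N = 0.013 s from regular monkey canal
  afferents, K = 1) is the conventional physiological prior; noise-free
  synthetic tables refit from it to 0.1 %.

## Psychophysics

The probability of a correct direction report is

    p(s) = 0.5 + (0.5 − λ)·Φ((ln s − μ)/σ),   λ ∈ [0, 0.05].

The reported threshold is e^μ. With λ > 0 this is not exactly the 75 %
point (p(e^μ) = 0.75 − λ/2); the convention is kept because the lapse is a
nuisance correction for response errors, not part of the sensory scale, and
it matches how such thresholds are conventionally reported. Maximum-
likelihood fitting runs L-BFGS-B on (μ, ln σ, λ) from three starting
locations; degenerate data (single stimulus level, or all-correct/
all-incorrect) are flagged and yield a boundary estimate instead.

The adaptive procedure maintains a posterior over a product grid of
(μ, σ, λ) with a uniform prior: μ on 41 points spanning the log stimulus
grid extended 20 % beyond both endpoints, σ on 21 log-spaced points in
[0.05, 1.5], λ ∈ {0, 0.0125, 0.025, 0.0375, 0.05}. All are configurable;
recovery tests cover the defaults. Each trial multiplies the posterior by
the Bernoulli likelihood; the next stimulus is the grid intensity
minimising the expected posterior variance of the threshold (expectation
over both outcomes under the posterior predictive), with ties resolved to
the lowest intensity. Variance minimisation rather than entropy was chosen
to match the variance-based stopping rule. The estimate and its variance
are computed on the linear deg/s scale (posterior moments of e^μ), because
break values and accuracy bounds are stated in deg/s; a log-scale variant
sits behind `variance_scale="log"`.

A session stops once the estimate variance has been below the break value
for 20 consecutive trials and at least 80 trials have run; a hard cap of
300 trials (well above the longest sessions seen in practice) guarantees
termination. Directions are equiprobable ±1 per trial and the performance
model is direction-symmetric.

The break value is calibrated by running fixed-length sessions (200 trials
by default) on a set of simulated observers, treating the final estimate
as the best attainable, and returning the largest variance level such that
every calibration trial whose variance falls below it has its running
estimate within 10 % (configurable) of that best estimate. This mirrors
how such stopping criteria are calibrated in practice; note it controls
the distance to the *long-run estimate*, not to the true threshold — the
residual long-run estimation error is set by the observer's σ and the
session length, and for a wide observer (σ = 0.4) it remains a
non-negligible fraction of the 10 % band (the acceptance suite measures
exactly this).

## Synthetic data

The bundled threshold table (nine conditions, asymmetric log-scale SEMs) is
shipped as packaged CSV and treated as already corrected for platform
peak-velocity offsets at 3 Hz. `generate_experiment` replays the whole
study: model-true thresholds define log-normal observers (μ = ln
threshold), adaptive sessions estimate them on the per-period stimulus
grids (20 log-spaced intensities; 0.045–7.2, 0.053–8.4 and
0.117–13.333 deg/s for T = 0.3, 1.4, 6.7 s), and the estimated table can
be refit to close the loop. `distort_profile` applies per-harmonic
attenuation plus additive white velocity noise; it is deliberately generic
— it exercises the measured-profile code path but does not emulate any
specific motion platform, whose true dynamics are not published.

What passing synthetic tests do **not** show about real data: simulated
observers are stationary (no learning, fatigue or bias drift), lapses are
stimulus-independent, and commanded profiles are reproduced perfectly
except where distortion is explicitly injected. In particular, parameter
values fitted to thresholds via *commanded* shapes are conditional on that
choice of model input: feeding measured (noisy, high-frequency-rich)
platform recordings into the same fit systematically lowers K and raises
τ_N, because recorded noise passes through the lead term and the `s`
numerator and inflates peak responses. Comparisons between parameter sets
are only meaningful for a fixed choice of input profiles.

## Known limitations

- Deterministic sensory stage: all trial-to-trial variability lives in the
  psychometric model, none in the canal simulation.
- A single noise level across frequencies; frequency-dependent neural
  noise would be absorbed into the fitted time constants.
- The 20-level stimulus grids quantise what an adaptive session can learn:
  for near-deterministic observers the threshold is only localised to
  within a grid gap (~27 % in log units), which bounds worst-case recovery
  accuracy regardless of session length.
- With the default 41-point μ grid, posterior means for very sharp
  observers inherit grid-resolution error; increase `n_mu` when simulating
  observers with σ well below 0.1.
- Yaw rotation about an earth-vertical axis only; no otolith contribution,
  multi-axis motion, or threshold definitions other than 75 %-correct peak
  velocity.
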
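# Methods

This note documents the models implemented in `nervedose`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generators do and do not emulate.

## The sigma ratio

A hook-electrode recording of the auditory nerve contains compound
spiking: many afferents firing biphasic extracellular spikes that
summate. The response statistic is computed by

1. subtracting the mean of the pre-stimulus baseline span (DC removal),
2. full-wave rectification (absolute value),
3. integrating the rectified trace over each 0.5 s tone window
   (left Riemann sum × sample period),
4. averaging over the repetitions of each SPL, and
5. dividing by the mean area of non-overlapping 0.5 s windows tiling
   the 60 s baseline span (120 windows at the defaults).

Because every repetition shares the same denominator, the mean of
per-repetition ratios equals the ratio of means; the code computes the
latter and the test suite asserts the identity. σ is invariant to
overall gain and DC offset of the recording, which the property tests
check. Rectification is full-wave: half-wave rectification would
discard half of a symmetric biphasic waveform and is not standard for
compound-activity quantification. The tone window is
`[onset, onset + 0.5 s]` with no latency offset. Background windows
between tones can be added to the denominator
(`include_intertone=True`) but the default denominator is the initial
baseline only; with a symmetric background process the two choices
agree in expectation. Acquisition-side band-pass filtering is treated
as a hardware property; an optional first-order high-pass
(`nerve_signal.highpass`) exists for recordings that arrive unfiltered.

## Synthetic nerve traces

The generator emulates the statistics of compound nerve activity, not
its biophysics. Background activity is a homogeneous Poisson
superposition of biphasic kernels (positive then negative half-sine
lobe, 0.5 ms per lobe, 40 µV amplitude); the two lobes cancel exactly,
so the process has zero mean. Gaussian instrument noise (10 µV SD) is
added. The default background rate of 800 compound spikes/s represents
the summed spontaneous activity of the ~80 afferents in the nerve.

**Rate calibration.** During each tone the spike rate is set so that
the *expected* σ at that SPL equals a target 4PL curve. The marginal
characteristic function of shot noise plus Gaussian noise is, by
Campbell's theorem,

    phi(t) = exp( r Σ_j (cos(t k_j) − 1)/sr − s_n² t²/2 ),

(the imaginary part vanishes because the kernel's samples occur in ±
pairs), and the expected rectified level follows exactly as
E|x| = (2/π) ∫ (1 − phi(t))/t² dt. This is monotone in the rate r, so
the tone rate solving E|x|(r) = σ_target · E|x|(r_background) is found
by bracketed root-finding; the Gaussian variance approximation
E|x| ≈ sqrt(2(r·∫k² + s_n²)/π) seeds the bracket. The quadrature
calibration was adopted because the Gaussian approximation leaves a
~10% upward bias in σ at high rates (the baseline marginal is
leptokurtic at sub-unit kernel overlap); the exact mapping recovers the
generating curve to a few percent, verified against a brute-force
kernel-superposition Monte Carlo in the test suite.

Presentation order is ascending SPL with a 1.0 s inter-tone gap (so
background-equivalent windows exist between tones); both are recorded
in the annotations. The 2 ms acoustic ramps are not modelled in the
rate profile — their effect on a 0.5 s integration window is below a
percent. Spike amplitude saturation at loud SPLs is not modelled:
superposition is linear by assumption.

## Dose-response tables

`simulate_dose_response` draws, per animal × SPL,

    sigma = fourpl(SPL; group truth) + u_animal + e,
    u_animal ~ N(0, 0.5),  e ~ N(0, 0.3),

with default group truths (b = −0.15, c = 1, d = 8, e = 75 dB) for
control and (d = 5, e = 85 dB) for noise-exposed animals — a healthy
ear saturating near σ ≈ 8 with threshold near 75 dB, and an exposed ear
with reduced maximum and raised threshold — and 9 animals per group,
the hook-electrode cohort size of the study conditions. Because σ is a
ratio of areas and strictly positive while the generative model is
additive Gaussian, draws are floored at 10⁻⁶; at the default noise
levels the floor is hit in well under 0.1% of rows. A consequence of
these small variance components is that the synthetic between-group
effect sizes at loud SPLs are much larger (|d| ≈ 6–9) than typical
real recordings; they are conditions for exercising the machinery, not
forecasts of real effect magnitudes.

## 4PL fitting and the treatment F test

`fit_fourpl` minimises least squares with an analytic Jacobian
(trust-region reflective, tolerances 10⁻¹³) from a heuristic start
(c₀ = min y, d₀ = max y, e₀ = SPL nearest the half-response,
b₀ = −4·slope/(d₀ − c₀)) plus seven jittered restarts by default.
Simulation studies inside the package use 4 restarts — the exact-data
and random-search tests show the heuristic start alone reaches the
optimum on curves of this family, and the restarts guard pathological
noise draws. The covariance is s²(JᵀJ)⁻¹ at the optimum; the
`converged` flag reports the optimiser status honestly.

The full treatment model is one 4PL per group (8 parameters); the
reduced model is a single pooled 4PL (4 parameters). To guarantee
numerical nesting (rss_full ≤ rss_reduced), the pooled fit is seeded
with both group solutions and each group fit with the pooled solution.
The extra-sum-of-squares statistic

    F = ((rss_reduced − rss_full)/4) / (rss_full/(n − 8))

is referred to F(4, n − 8). When both models fit exactly there is
nothing for treatment to explain and F = 0; a vanishing full-model rss
with genuine reduced misfit reports F = +∞ with a diagnostic.
Per-parameter tests are Wald t statistics from the two *independent*
group fits (difference over the root summed variances, df = n − 8);
whether a joint 8-parameter covariance would be preferable is
undecidable from the available description of the original analysis,
and independent fits are the simpler, documented choice. p values are
reported raw, without multiplicity correction, matching per-day
reporting. Under a shared-truth null with Gaussian residuals the test
suite verifies the rejection rate at α = 0.05 lies in the binomial 95%
band and the p values pass a Kolmogorov–Smirnov uniformity test —
the F reference distribution is exact only for linear models, but at
these sample sizes the nonlinear distortion is negligible.

The tympanal power law is fitted by OLS of log₁₀(displacement) on SPL
restricted to points above the noise floor; the slope per dB times 20
is the exponent with respect to sound pressure (p = 10^(SPL/20)). Two
points are accepted (they determine an exact line); the floor-exclusion
contrast test shows the bias incurred when floor-level points are
retained.

## Linear mixed models

`fit_lmem` implements Gaussian LMEMs with up to two crossed random
intercepts by direct dense linear algebra — the datasets here are at
most a few thousand rows, where an n × n Cholesky factorisation is both
simple and fast. With variance ratios λ_g = σ²_g/σ²_ε, the scaled
covariance V* = I + Σ λ_g Z_g Z_gᵀ is factored, β is profiled out by
GLS and σ²_ε analytically, leaving a search over λ alone. The REML (or
ML) criterion and its *analytic* gradient in λ are minimised by
bounded L-BFGS-B from a fixed start grid ({0.01, 0.5, 5}, plus
anisotropic points for two components), making the fit deterministic
and locating variance components to ~10⁻⁸ relative precision (the
balanced-design closed form is reproduced to 1e-8 in the tests, and a
50-row crossed fixture matches an independent mixed-model
implementation to 1e-4 in the fixed effects). REML is the default
criterion; ML is selectable in the model spec. Ratios below 10⁻⁷ are
clamped to zero and flagged as boundary estimates.

Satterthwaite degrees of freedom for a contrast c follow the lmerTest
construction: df = 2g²/(∇gᵀ A ∇g) with g(θ) = Var(cᵀβ̂) as a function
of the variance components θ, ∇g by central finite differences
(step = ∛ε × component scale) and A the inverse expected information
of the REML criterion, I_ij = ½ tr(P V_i P V_j). In the boundary/OLS
limit df = n − p exactly; df is clamped to (0, n − p]. Balanced
two-group designs recover the classical 2g − 2 between-animal df, and
Wald–Satterthwaite 95% intervals achieve 93–97% empirical coverage at
16 animals in the calibration suite.

Categorical fixed effects are dummy-coded with the first sorted level
as reference (so `control` is the reference treatment); SPL enters
fixed effects as a continuous covariate and its random-intercept role
as a factor. Both "SPL as a random intercept alongside animal" and
"animal only" specs are expressible; neither is hard-coded.

Cohen's d is the plain pooled-SD standardised difference
(n₁ + n₂ − 2 denominator), signed as first argument minus second.

## Power analysis

`t_test_power` evaluates the noncentral-t distribution with
df = n₁ + n₂ − 2 and noncentrality d·√(n₁n₂/(n₁ + n₂)) beyond the
central-t critical value; the tests verify it against an independent
chi-square quadrature oracle and a 200 000-replicate Monte Carlo.
`a_priori_n` returns the smallest even total N (equal groups) reaching
a target power, searched from the normal-approximation start; at
d = 1.45, 95% power and one-sided α = 0.05 this gives N = 24. The
one-sided test is the default because it is the sidedness under which
that design-stage target is met at the stated power; the two-sided
variant is available and yields a larger N.

`simulate_power_lmem` is the simr-style procedure: repeatedly generate
dose-response data from a configured truth, fit the requested model and
count rejections of the treatment term by its Satterthwaite p value at
α. Replicate seeds are spawned from a root seed, so the estimate is
bit-reproducible and chunkable; more than 5% non-converged replicates
abort the estimate. The original study simulated from a model fitted to
earlier raw recordings that are not redistributable; the procedure here
is therefore reproduced in form against configurable truths.

## Pipeline and I/O

Waveforms travel as float32 single-channel WAV plus a JSON sidecar
(protocol, annotations, seed, config hash); tables as UTF-8 CSV with
mandatory headers, '.' decimals, full round-trip float precision
(`float_precision="round_trip"` on read); fits and reports as JSON.
Units: SPL in dB SPL, waveform samples in µV, displacement in nm, width
in µm. Schema validation pinpoints offending rows before any compute.
`run_pipeline` executes trace → σ → dose fit → LMEM → power in
dependency order, writes a manifest with the SHA-256 of every artifact
(no timestamps, so reruns are byte-identical), and halts with
stage-attributed errors while retaining partial outputs. The replay's
treatment flag compares the observed F to the 95th percentile of the
pipeline's own null simulation (shared pooled-fit truth, matched
design and residual scale).

## Problem sizes

Simulation studies in the tests and the acceptance script use: 1000
replicates for the null-F calibration (30 animals/group), 500
simulations for interval coverage and for each power estimate, 200
seeds for 4PL recovery, and a 6-animal-per-group waveform-level replay
over five SPLs at 12.5 kHz — sizes at which every Monte-Carlo band in
the suite is decisive while the whole pipeline remains runnable on a
laptop in minutes.

## Known limitations

- The trace generator models rate changes only: no adaptation within
  the tone, no onset synchronisation, no amplitude saturation of
  summating spikes, no frequency tuning. Waveform-level replays give
  every animal in a group the same underlying curve, so between-animal
  spread there reflects recording noise only (dose-response *tables*
  do include animal-level heterogeneity).
- The F test's reference distribution is asymptotic for nonlinear
  models; calibration is verified at the study's sample sizes, not for
  very small designs.
- The replay's null-F threshold is calibrated with homoscedastic
  table-level simulations, while σ tables derived from waveforms have
  noise that grows with the response level; the trace-level null F is
  therefore somewhat heavier-tailed than the threshold assumes, and
  borderline flags from waveform replays should be read accordingly.
- Random *slopes*, non-Gaussian responses and Kenward–Roger corrections
  are out of scope; Satterthwaite df at severely unbalanced or
  few-level groupings inherits the usual approximation error.
- Cohen's d on synthetic dose-response data at loud SPLs is much larger
  than in typical real recordings (see above).
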
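# Methods

## Oxygen mass-balance model

The state-space model treats the 30-minute dissolved-oxygen record of
one sunrise-to-sunrise day as noisy observations of a latent "true" DO
trajectory. Conditional on the day's parameters the transition is
affine,

    x_{i+1} = a_i x_i + b_i + ε_i,          ε_i ~ N(0, σ_p²)
    a_i = 1 − K_T,i Δt
    b_i = I·Q_p,i − ρ20·θ^(T_i−20) + K_T,i Δt [O2,sat](T_i)
    y_i = x_i + η_i,                        η_i ~ N(0, σ_o²)

with Δt = 0.5 h and one explicit-Euler step per observation interval.
The initial state is the parameter `o2_init` (DO at sunrise), which is
why days are cut sunrise-to-sunrise: the initial condition is then a
physically interpretable quantity near the diel minimum. Because the
system is linear-Gaussian given the parameters, the latent states are
marginalised *exactly* by a scalar Kalman filter; missing observations
are simply skipped in the update and bridged by the prediction, never
interpolated. The filter is verified against dense numerical quadrature
over the latent states on short days (relative error < 1e-6).

Assumptions inherited from the formulation: a single well-mixed layer
of fixed depth (0.5 m default), linear photosynthesis–irradiance
response (no saturation or photoinhibition), aerobic respiration only,
and no advection. Under hypoxic-to-anoxic conditions the oxygen method
understates total heterotrophic metabolism.

## Components

**Light.** Q_p = peak_qp · max(0, sin(solar elevation)), with
declination and the equation of time from the Spencer low-precision
series (≈1-minute accuracy, ample at 30-minute cadence) and uniform
atmospheric transparency. Only the diel *shape* matters: the
coefficient I absorbs the absolute scale (verified by a scale-invariance
test), so peak_qp defaults to a nominal tropical clear-sky
2000 µmol photons m⁻² s⁻¹.

**Gas exchange.** O₂ solubility from the Benson–Krause fit at salinity
0 (9.09 mg L⁻¹ at 20 °C), scaled linearly with pressure (default
1 atm; the simple Henry proportionality, no vapour-pressure
refinement). Schmidt numbers from the freshwater O₂ cubic polynomial
(Sc(20) = 530.5); temperature standardisation uses exponent ½
(wind-roughened surface): K20 = K_T·(Sc(T)/Sc(20))^½. Wind-based
priors use k600 = 0.266·u10² (cm h⁻¹) and K20 = k600/100/z_mix — the
wind-derived velocity is treated as the 20 °C velocity, a ≈6%
simplification of the full Sc-600→Sc(20) chain. Prior sd is
max(0.3·mean, 0.02) h⁻¹, a 30% relative uncertainty typical of
wind–k600 regressions; without wind the prior is uniform(0, 4) h⁻¹.

**Priors and sampling.** I ~ U(0, 0.05) (mg L⁻¹ step⁻¹ per
µmol m⁻² s⁻¹), ρ20 ~ U(0, 2) mg L⁻¹ step⁻¹, o2_init ~ U(0, 20) mg L⁻¹,
σ_p, σ_o ~ U(10⁻⁴, 1) mg L⁻¹; θ = 1.047 (the conventional metabolic
temperature coefficient), all configurable. σ_o is a property of the
sonde, so `fit_campaign` shares it across days (first pass estimates it
freely on up to 10 days, second pass fixes the pooled median); σ_p is
per-day, letting some days be more stochastic than others. Sampling is
adaptive random-walk Metropolis on the marginal (state-integrated)
posterior: a short component-wise warm-up, then joint Gaussian
proposals whose covariance is the running chain covariance
(Haario-style, 2.38²/d scaling tuned to 0.234 acceptance) — necessary
because GPP, ER and K20 lie on a strong posterior ridge. All
adaptation stops at the end of burn-in. Default protocol: 3 chains ×
35,000 iterations, 20,000 burn-in, thinned to 7,500 saved draws;
`FAST_CHAINS` (3 × 8,000, 4,000 burn-in, thin 5) is used for batch and
simulation work. Chains start from a jittered coarse-grid +
Nelder-Mead MAP estimate. Convergence gate: split-chain R̂ < 1.05 and
lag-10 autocorrelation of thinned draws < 0.3. The sampler is
cross-checked against an independent ensemble sampler (emcee) on the
identical log-posterior.

**Sufficiency filter.** "Enough diel signal to report" is
operationalised as: observed diel DO amplitude > 3 × posterior median
σ_o, and the convergence gate passes. The rule is a package choice and
is recorded in the output metadata (`summary.attrs`).

**Summaries and correlations.** Daily oxygen statistics flag hypoxia
at 2 mg L⁻¹ both on the daily mean and on any step, and report percent
saturation (and below-saturation fractions) both ways since either
convention appears in field reports. Monthly aggregates average rate
fields over days passing the sufficiency filter only; months with
fewer than 3 sufficient days are excluded from correlation analysis (a
monthly mean of 1–2 days is unstable). Monthly-scale relationships use
Pearson r with a Student-t test (α = 0.05), daily-scale ones
tie-corrected Kendall τ-b (exact null for n ≤ 10 without ties).

**Carbon and fisheries accounting.** aNPP = GPP × 0.6 / 1.2 ×
(12.011/31.998) ≈ 0.1877 × GPP (net production 60% of gross,
photosynthetic quotient 1.2, O₂→C by molecular mass). PPR =
B_C·(1/Q)^(TL−1) with B_C = catch/4 × 0.446. Percentages of reference
aNPP are reported to the nearest integer.

## Synthetic campaigns

The generator runs the exact model transition forward with process and
observation noise, so fitted and generating models coincide by
construction — campaigns test *estimation*, not model adequacy. Daily
GPP/ER targets are lognormal around preset means and converted to
(I, ρ20) through each day's light and temperature sums, so the truth
table is exact in closed form; K20 derives from daily wind through the
same gas pipeline the priors use; water temperature is a diel sinusoid
(mean 30 °C, amplitude 1 °C, peak 15:00 — near-isothermal dawns,
afternoon surface warming). DO has a hard floor at 0 mg L⁻¹
(truncation, counted and logged; rare by design in the presets). Noise
defaults: σ_p = 0.05 mg L⁻¹ per step, σ_o = 0.2 mg L⁻¹.

Presets: `net_heterotrophic` (GPP ≈ 4, ER ≈ 25 g O₂ m⁻³ d⁻¹, CV 0.25,
wind 6–10 m s⁻¹ so reaeration balances the deficit above anoxia),
`hypoxic` (GPP 6.5, ER 12, CV 0.05, calm wind 2.7–2.8 m s⁻¹ → K20 ≈
0.04 h⁻¹; nightly minima near 1–1.5 mg L⁻¹, below 2 on most days but
clear of the floor), `balanced` (GPP = ER = 5, brisk wind; DO tracks
saturation). The tight day-to-day spread in the hypoxic preset is
deliberate: with realistic spread the lower tail of nightly minima
reaches anoxia and truncation stops being rare.

What the generator does *not* emulate: mixing-depth dynamics, advection
and flood-stage transport, sensor drift/fouling, cloud, and any
model-structure error (nonlinear P–I, anaerobic metabolism). Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness of the
method on real sonde data.

## Numerical choices and problem sizes

Sunrise/sunset by bisection of the solar-elevation sign change to ≤1
minute. Segments are unusable if >10% of steps are missing or any gap
exceeds 2 h (routine sonde servicing survives; failures do not).
Degenerate likelihood (σ_p = σ_o = 0) returns 0 on data consistent
with the deterministic path and raises otherwise. Seeds propagate
through `numpy.random.SeedSequence`; identical seeds give bit-identical
chains. Simulation studies in the test suite use 30–110-day campaigns
and the reduced chain protocol, sized so the full suite runs in a few
minutes on one CPU; the recovery study uses 40 days at the field-like
net-heterotrophic magnitudes with σ_o = 0.2 mg L⁻¹.

## Known limitations

Daily GPP posteriors are information-limited by the process-noise ×
reaeration-prior combination: at σ_p = 0.05 mg L⁻¹ step⁻¹ and a 30%-sd
K20 prior, single-day GPP medians carry ~12% typical relative error
(dropping below 10% only when process noise is several-fold smaller),
with 95% intervals that remain well calibrated (≥95% empirical
coverage). ER and K20 are partially confounded; the wind-informed
prior, not the diel curve alone, is what pins ER's absolute level. The
single-layer assumption fails where thermoclines develop, and surface
bloom production exchanging directly with the atmosphere is
under-counted.
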
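# Methods

## Scope and intent

`magnetoferm` couples a closed-loop digital twin of a 3 L oxystat batch
fermentation of *Magnetospirillum gryphiswaldense* with the analytics used to
quantify growth and magnetosome production: rate/yield estimation from time
series, TEM-style particle statistics, and SAXS size decomposition.  All data
are synthetic (generated by the plant model and emulators) or entered as
printed summary tables; nothing here fits raw experimental data.

## Plant model

State vector: biomass X (OD₅₆₅), lactate S (mM), nitrate N (mM), dissolved
oxygen C (% air saturation), cellular iron w (mg g_dw⁻¹), the running
magnetosome size distribution (mean, sd; nm), and a low-pass-filtered
regulatory oxygen signal C_reg (first order, τ = 0.5 h) that drives the
Fnr-type denitrification switch: transcriptional regulation cannot follow
the second-to-minute-scale dO₂ dips that closed-loop control at 1 %
produces, and without the filter those dips would transiently derepress
denitrification and inflate the emergent microoxic nitrate consumption from
the calibrated ~1.1 to ~1.5–1.9 mM h⁻¹ OD⁻¹.

**Growth.**
μ = μ_max · S/(K_S+S) · A(C, N) · (1 − s·C), with the electron-acceptor
availability

A = min[ C/(K_O₂+C) + η · K_fnr/(K_fnr+C) · N/(K_N+N), 1 ].

The Fnr-type factor K_fnr/(K_fnr+C) represses nitrate respiration under
oxygen; the linear term (1 − s·C) models oxidative-stress attenuation; the
cap at 1 expresses that both acceptors together cannot exceed full
respiratory capacity (this is what makes 1% dO₂ the growth optimum: nearly
full O₂ respiration plus derepressed denitrification).  The mechanistic
constants are *derived* from three anchor growth rates (0.07, 0.15,
0.13 h⁻¹ at 95%, 1%, and 0% dO₂/10 mM nitrate respectively, at saturating
substrate), in closed form:

- s = (1 − r)/(95 − r) with r = μ₉₅/μ₁  → 0.00564 per %,
- μ_max = μ₁/(1 − s) → 0.1509 h⁻¹,
- η = μ₀ / (μ_max · 10/(K_N+10)) → 0.870.

Moving an anchor automatically recalibrates the model
(`scripts/calibrate_kinetics.py` prints the residuals; all anchors are
reproduced within 1%).  Half-saturation defaults: K_S = 0.1 mM,
K_O₂ = 0.05 %, K_N = 0.1 mM (high-affinity; they shape only the terminal
approach to depletion), K_fnr = 0.08 % — anchored so that the emergent
microoxic nitrate consumption is 1.09 mM h⁻¹ OD⁻¹ (0.71 assimilatory +
respiratory share at 1% dO₂) rather than a naive ~1 % half-repression
constant, which would over-predict microoxic denitrification threefold.

**Substrates.**  Lactate uptake is growth-coupled through a single yield,
dS/dt = −(μ/Y)·X with Y = μ₁/q_lac = 0.15/4.63 OD per mM, so yield
conservation ΔX = Y·ΔS holds identically along any trajectory (verified to
1e-6 relative; the integrator runs at rtol 1e-9).  Nitrate uptake is not
growth-coupled: dN/dt = −[q_assim + q_resp·K_fnr/(K_fnr+C)] · N/(K_N+N) · X
with q_assim = 0.71 and q_resp = 5.48 mM h⁻¹ OD⁻¹ (the Fnr factor evaluated
at C_reg), reproducing 0.71 / 1.09 / 6.13 mM h⁻¹ OD⁻¹ at 95 / 1 / 0 % dO₂.
At the default 4 mM microoxic nitrate the budget is tight: nitrate outlasts
the main-growth window but co-depletes with lactate near the end of the
batch, after which growth proceeds on oxygen alone — growth limitation
remains lactate-side, which is the substantive behaviour.  Consumption is gated
off before the lag time (otherwise a 13 h anoxic lag would consume half the
nitrate before growth starts); oxygen uptake is *not* gated — resting cells
respire, and that respiratory load is what the controller works against
from inoculation.

**Oxygen.**  dC/dt = k_La(rpm, Q)·(C*·y_O₂/0.21 − C) − q_O₂·X·C/(K_O₂+C),
with k_La = a·(rpm/100)^α·Q^β + k_s·(rpm/100) (a = 0.4, α = 2, β = 1.5,
k_s = 0.25 h⁻¹).  Two deliberate, non-textbook choices:

- β = 1.5 (textbook sparged-tank exponents are ~0.2–0.8).  The airflow
  actuator is quantized at 0.1 SLPM; with a sub-linear exponent the first
  airflow quantum at 300 rpm jumps the transfer capacity by an order of
  magnitude, which makes the 1 % set point oscillate violently.  A
  super-linear exponent gives fine resolution at low flow while
  (300 rpm, 10 SLPM) still yields k_La ≈ 115 h⁻¹ — enough to hold 95 %
  dO₂ against the uptake of an OD 0.76 culture, which is the calibration
  constraint for q_O₂ = 600 %-sat h⁻¹ OD⁻¹ (≈ 5 mmol O₂ g_dw⁻¹ h⁻¹, a
  plausible bacterial uptake capacity).
- the surface-aeration floor k_s·(rpm/100) keeps k_La positive at zero
  airflow but is small enough that oxygen ingress at minimum actuation
  stays below the inoculum's uptake — otherwise a 1 % set point could not
  be held early in the batch at all (the cascade has no N₂ blending).

**Iron, size, C_mag.**  Cellular iron relaxes first-order (k = 0.12 h⁻¹)
toward a dO₂-dependent target interpolated through (0 %, 25.3), (1 %, 14.4),
(5 %, 4.0), (95 %, 3.3) mg g_dw⁻¹ — the extra 5 % anchor encodes the sharp
inhibition of biomineralization above ~5 % dO₂.  The magnetic response
C_mag is a monotone piecewise-linear map of iron through (3.3, 0.10),
(14.4, 0.74), (25.3, 0.99): both quantities are reported measurements but no
transfer law is published, so the map is a calibration, not a model.

**Integration.**  LSODA (stiff-capable, adaptive) with rtol 1e-9/atol 1e-12;
non-negativity by derivative projection plus state clipping; in closed loop
the plant advances one controller interval at a time under zero-order-held
actuators, and the lag discontinuity is split at an integration boundary.
An analytic oracle validates the solver: with constant μ and q the anoxic
nitrate-depletion time is t = ln(1 + S₀μ/(qX₀))/μ; the ODE agrees within
0.1 %.

## Controller

Discrete PI at 1-min sampling: e = set point − measured reading,
I ← clamp(I + e·Δt), u = clamp(k_p·e + k_i·I, 0, 100), with anti-windup by
freezing I while u is saturated in the error's direction.  The split-range
cascade maps u ≤ 50 % to the agitation ramp (floored to 10 rpm steps,
airflow 0) and u > 50 % to the airflow ramp at maximum agitation (rounded
to 0.1 SLPM).  Quantization *is* the "stepwise" actuation; no schedule is
imposed.

Gains: k_p = 5, k_i = 40 h⁻¹, selected with `scripts/tune_controller.py`.
The decisive constraint is the 1 % set point: dO₂ cannot go below zero, so
the usable error is bounded by ~1 percentage point and the integral term can
slew at most k_i·1 output-% per hour, while the culture's oxygen demand
drives the required controller output upward at several %/h during the main
growth phase.  k_i ≳ 25 h⁻¹ is needed to track; k_i = 40 gives 35 h trace
medians of 94.97 (95 % set point) and 0.84–0.86 (1 %) across seeds, with the
fluctuation bursts at 1 % during main growth (actuator-quantization limit
cycling plus probe noise near the detection floor) emerging from the model
rather than being scripted.  Both noise and quantization are configurable,
so their separate contributions to the fluctuations can be studied.

## Sampling emulators

`observe` produces at-line observations: subsampling at a fixed interval,
multiplicative log-normal noise (log-sd = CV, so log-linear rate fits are
unbiased) on OD/lactate/nitrate/iron, additive truncated-Gaussian noise on
dO₂ (sd in percentage points; the spec scalar is reused as the absolute sd).

`sample_particles` emulates TEM counting (~1000 particles per replicate,
triplicates): Gaussian diameters around the measured per-regime trajectory
(time-interpolated, non-positive draws rejected), and a per-cell table
generated from a *density* model — magnetosomes per µm of cell length drawn
per cell, count = round(density × length), with lengths from a truncated
Gaussian (> 1.5 µm).  The density parametrization centres the MS µm⁻¹
statistic on the tabulated values; drawing counts and lengths independently
would inflate the mean per-cell ratio by ~5 % through the 1/length moment.
The real empirical size distributions are visibly non-Gaussian (heavier
small-diameter shoulder in the violin plots), so Gaussian emulation is an
approximation: pooled means/sds are matched exactly, but the >30 nm
exceedance fraction computed from Gaussian samples lands ~0.7–1.5
percentage points away from the empirical 66.4 %/48.0 %, which is why those
comparisons carry ±3-point tolerances.  Passing tests demonstrate pipeline
correctness on distributions with the printed first two moments, not
distributional realism.

## Analytics conventions

- Growth rate: least-squares slope of ln OD vs time over a declared window;
  per-condition default windows 12–18 h (95 %), 10–17 h (1 %), 17–23 h
  (0 %); a max-slope auto-detection is available behind a flag.
- Consumption: (−slope of concentration) / time-averaged OD over the same
  window — robust to sampling jitter and dimensionally mM h⁻¹ OD⁻¹ directly.
- Doubling time ln 2/μ is computed per replicate and then pooled; pooled
  ln2/mean-μ and mean of per-replicate doubling times differ at the few-%
  level, which is why both are exposed.
- The OD→dry-weight conversion (default 0.286 g L⁻¹ per OD, from a 0.4 g
  L⁻¹ ≙ OD 1.4 correspondence) is an explicit argument of every
  dry-weight-dependent quantity, never a hidden constant — published yield
  and productivity figures depend on an unstated conversion and cannot all
  be reproduced with any single value.
- Magnetite productivity: (fraction bound in magnetite, default 0.99) ×
  iron × biomass × M(Fe₃O₄)/(3 M(Fe)) / process time.

## Wilcoxon rank-sum

Midranks throughout.  Exact mode enumerates all C(n, n_a) rank assignments
(limited to n ≤ 12; two-sided p doubles the smaller tail, capped at 1);
otherwise a normal approximation with tie-corrected variance and 0.5
continuity correction.  The two modes agree within 10 % relative p wherever
the exact p is ≥ 0.05; in the extreme tail of such small samples the
discrete exact distribution and any continuous approximation necessarily
diverge (at n = 6+6 the smallest exact two-sided p is 2/924 ≈ 0.0022 while
the corrected normal gives 0.0051), so tail agreement is not claimed and
the exact mode should be used for small samples.

## SAXS

- Sphere form factor with the analytic small-x series below x = 1e-3;
  zeros at the roots of tan x = x (first root 4.49340946, validated against
  a bracketed root-finder in the tests).
- Polydispersity: Gaussian in *diameter* (the "±" of a fitted size is read
  as the distribution sd), R⁶-weighted quadrature over ≥ 51 nodes truncated
  at ±4 sd with non-positive diameters excluded, normalized so
  I(0) = scale + background.  At the magnetosome polydispersity (~18 %) the
  first minimum is fully smeared in I(q); it survives in the Porod-scaled
  curve I·q⁴, which is what the minimum-locator and the fit initializer
  use.  Dilute (no structure factor) modelling is used for analysis: chain
  correlations affect mainly the lowest q, while the size-determining
  features are form-factor-driven.
- Guinier: ln I vs q², Rg = √(−3·slope), validity flagged at q_max·Rg ≤ 1.3
  (standard bound; fits are accurate to ~2 % at the bound, with the
  systematic part of that error coming from the q⁴ term of the sphere
  expansion).  Solid-sphere conversion R = √(5/3)·Rg.
- Membrane/core decomposition: R_membrane from the Guinier Rg of
  magnetite-free (aerobic) samples (Rg = 1.3 nm → 1.7 nm), core diameter =
  overall 2R − 2·R_membrane.
- Flake analysis: thickness from the cross-section Guinier ln(I·q²) vs q²
  (T = √12·Rg_t), radial size from R = √(2(Rg_tot² − Rg_t²)) using the
  overall low-q Rg.  Windows are auto-selected (overall: iterated to
  q ≤ 1/Rg; thickness: q ∈ [3/R_est, 0.9/Rg_t]).  A `flake_like` flag
  (thickness < radius) discriminates platelets from compact scatterers.

## Determinism and seeds

Every stochastic element (sensor noise, observation noise, particle draws,
synthetic-curve noise) consumes a `numpy` Generator seeded explicitly;
identical seeds give bit-identical outputs.  The CLI fans a single run seed
out to per-module child seeds via `SeedSequence.spawn`, so modules can be
re-run independently yet reproducibly.

## Problem sizes

Default full-batch simulations cover 35 h at 1-min control sampling
(2101 samples); rate-recovery analyses use three replicate batches observed
every 30 min with 2 % noise; particle analyses use ~1000 particles ×
3 replicates; SAXS fits use 200–300-point curves.  These sizes match the
study design the package emulates.

## Known limitations

- Trajectory maxima are not reproduced: the printed per-regime rates,
  yields and OD maxima are mutually inconsistent under any single OD→dw
  conversion, and this package prioritizes rates (μ, q) — simulated OD
  maxima are ~0.29–0.56 versus reported 0.49–1.06.  Rate and median-control
  comparisons are unaffected.
- No pH/temperature/foam dynamics, no fed-batch feeding, no nitrite
  toxicity mechanism, no mechanistic crystal growth; the anoxic run is
  strictly open-loop.
- The SAXS toolkit does no 2-D reduction, smearing, or absolute-intensity
  calibration, and does not reproduce any specific commercial model zoo.
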
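# Methods

## The kinetic model

`unfoldkin` analyses single-turnover stopped-flow fluorescence
time-courses of a ring-shaped AAA+ motor (ClpB-class disaggregase)
unfolding a substrate made of an unstructured N-terminal binding tract
followed by tandem folded titin I27 domains, with a PIFE-reporting dye at
the C-terminus.  The motor is pre-bound; after mixing with ATP it
proceeds through `n` sequential rate-limiting unfolding steps with rate
constant `k_U` (s⁻¹) and finally dissociates from the C-terminal end
with rate constant `k_end` (s⁻¹).  Only the last intermediate (motor at
the dye) and the released unfolded product are fluorescent, with
amplitudes `F1` and `F2`; earlier intermediates are dark.  The observed
signal is

    F(t) = F1 · last(t) + F2 · product(t)

where `last(t)` is the occupancy of the last intermediate — the
convolution of a gamma(n, k_U) first-passage density with exponential
decay at `k_end` — and `product(t)` is the cumulative dissociated
fraction (the first-passage CDF of gamma(n, k_U) + Exp(k_end)).  When
`F1 > F2` the trace shows the characteristic lag → rise → decay with a
single interior maximum.

The step count is tied to substrate geometry, `n = (L − C)/m`: `L` is
the total length (aa), `C` the pre-translocated plus excluded length at
mixing (aa), and `m` the kinetic step-size (aa unfolded between two
rate-limiting steps).  `n` is treated as a real number (gamma shape
parameter) so the model is continuous in `m` during optimisation;
nothing in the analysis rounds it.

## Numerical evaluation

The last-intermediate occupancy reduces to

    last(t) = k_U^n/Γ(n) · e^(−k_end·t) · ∫₀ᵗ τ^(n−1) e^(−(k_U−k_end)τ) dτ.

* `k_U > k_end`: regularized lower incomplete-gamma closed form,
  assembled in log space.
* `k_U ≤ k_end`: the integral equals `tⁿ/n · M(n, n+1, z)` with
  `z = (k_end − k_U)t ≥ 0` (Kummer's function).  For moderate `z` it is
  summed as `n·e^z·Σ_k Poisson(k; z)/(n+k)` (all terms positive, no
  cancellation); for `z ≫ n` the standard large-argument asymptotic
  series is used.  `k_U = k_end` needs no special-casing (z = 0).
* `product(t)` is computed as `gammainc(n, k_U t) − last(t)`; where that
  subtraction would cancel (product ≪ CDF, i.e. early times) it is
  recomputed from the integration-by-parts form
  `∫₀ᵗ k_end·e^(−k_end·u)·G(t−u) du` (G the gamma CDF), a smooth,
  positive integrand handled by segmented Gauss–Legendre quadrature.

Two independent verification routes back these production paths:

* a matrix-exponential propagation of the (n+2)-state linear chain
  (`ode_oracle`, integer n), exact to machine precision — the analytic
  evaluation matches it to better than 1e−8 relative wherever occupancies
  exceed 1e−10 (below that the propagator's own absolute roundoff floor,
  ~1e−16, dominates the *relative* comparison);
* a segmented Gauss–Jacobi/Legendre quadrature backend (`backend="quad"`)
  valid for any real n — the Jacobi weight absorbs the `(1−w)^(n−1)`
  endpoint singularity exactly — plus an arbitrary-precision Talbot
  inversion of the Laplace transform (`talbot_reference`, mpmath),
  used in tests.  A double-precision fixed-Talbot inversion was evaluated
  and rejected: its roundoff floor (≈ eps·e^(2M/5), absolute) cannot meet
  the relative-accuracy contract on small occupancies.

Peak times are located by bracketed bounded minimisation from a coarse
log grid (accuracy max(0.1 s, 1e−4 relative)).  Note that when the
interior maximum barely exceeds the `F2` asymptote (fast `k_end`, large
`F2`) the peak location becomes ill-conditioned — flat to ~1e−11 over
hundreds of seconds — and no evaluator can localise it reproducibly;
the peak *value* remains well-defined.

## Synthetic data generator

`simulate_timecourse` produces raw traces
`baseline + labeling_efficiency · extent_of_binding · F(t) + noise`
on a log-spaced grid (default 10 ms – 5000 s, 2000 points, matching
stopped-flow acquisition and the slowest observed peaks).  Noise is
additive i.i.d. Gaussian with sd equal to `noise_sd` × the trace's peak
amplitude (default 0.02); photodetector noise at these signal levels is
well approximated as Gaussian, and proportional scaling keeps
signal-to-noise comparable across substrates.  Replicates draw from
independent streams spawned from `(seed, substrate, delay, replicate)`,
so generation is bit-reproducible.  Pre-translocation during the
ATPγS-only delay `Δt1` enters as `C(Δt1) = excluded_length +
v_γS · Δt1`.

Condition presets carry the study conditions (rates s⁻¹, lengths aa):

| preset | k_U | m | excluded length | v_γS | k_end per substrate |
|---|---|---|---|---|---|
| 1:1 ATP:ATPγS | 0.017 | 56.5 | 48 | 0.09 | 0.012 / 0.011 / 0.010 |
| ~3:1 ATP:ATPγS | 0.055 | 58 | 67 | 0.05 | 0.025 / 0.018 / 0.012 |
| ATPγS only | 0.0042 | 26 | 71 (fixed) | 0 | 0.008 / 0.005 / 0.003 |

Substrate lengths are 168/265/362 aa with labeling efficiencies
0.75/1.00/0.70 (the mid-length construct labels best and therefore shows
the largest peak).  Default amplitudes are `F1 = 4`, `F2 = 0.2` on a
baseline of 5 arbitrary units.

The per-substrate `k_end` values and the `F2/F1` ratio are only loosely
constrained experimentally (terminal dissociation is observed between
0.01 and 0.15 s⁻¹ with replicate-level variability).  They were fixed by
a forward analysis of the mechanism: only with slow terminal dissociation
(at or below `k_U`), a small `F2/F1` and a small spread of `k_end`
across substrates does the signal peak track the motor's arrival time
closely enough that the length-vs-peak-time slope reproduces `m·k_U`
within ~10% and the peak-time intercept bias stays nearly constant in
`Δt1` — the behaviour the kinematic analysis assumes and real data in
this regime display.  With fast dissociation or large `F2` the peak
flattens and drifts late, and the model-independent analysis degrades.

What the generator does *not* emulate: instrument dead time, shot-to-shot
chemical-equilibration drift (represented only through `C(Δt1)`),
photobleaching, and binding kinetics (extent of binding is a static
amplitude factor).  Passing closure tests therefore demonstrate that the
analysis inverts its own generative model, not that instrument-specific
artefacts are handled.

## Preprocessing

Relative fluorescence enhancement is `|F0_avg − F(t)|/F0_avg` with
`F0_avg` the mean of the first `n_baseline` points (default 10 — well
inside the lag at the rates of interest, and enough points for a robust
mean).  The ratio is invariant to the raw amplitude scale.  Replicates
are averaged pointwise (mean ± sample sd) only on identical grids;
mismatched grids are an error, never silently interpolated.  Smoothing
is Savitzky–Golay in index space (`mode="interp"` at the edges),
optional and off by default — noiseless analysis needs none, and the
peak refinement parabola provides sub-grid resolution.

## Model-independent analysis

Substrate length is regressed on peak time (weighted by replicate
peak-time scatter, 1/sd²; unweighted when scatter is degenerate):
slope = overall unfolding/translocation rate (aa/s), intercept = the
pre-translocated distance `C`.  Per-delay intercepts regressed on `Δt1`
give the ATPγS-driven rate (slope) and the excluded length (intercept).
The finite-step-count peak offset biases every intercept by a nearly
`Δt1`-independent constant (a few aa in the study regime), so it cancels
in the `Δt1` slope but is inherited by the excluded length; no
correction is applied, and the per-delay slopes agree with each other
only at the ~0.5% level even on exact data.

## Model-dependent analysis

All substrate traces are fit simultaneously: `m` and `k_U` global,
`k_end` local, with `n_i = (L_i − C_i)/m` and `C` supplied per trace
(from the peak-time intercepts, or from the manifest in closure tests so
the two stages can be validated independently).  `F1`/`F2` are local:
labeling efficiency and the refolding contribution to the signal differ
per substrate.  The optimizer is multi-start (default 10 seeded starts)
bounded trust-region least squares over log-rates and log-`m`
(bounds: rates 1e−4–10 s⁻¹, m 5–200 aa); the amplitudes are solved
exactly at every step by non-negative least squares on the two-column
species basis (variable projection), which removes them from the search
space.  Residuals are unweighted within and across traces.  The fit
refuses to report when its two best optima differ by <1% in objective
but >20% in the shared parameters (multimodality guard), and flags the
`m`–`k_U` degeneracy when only one substrate length is supplied.

A diagnostic local-`n` mode frees `n` per trace with `k_U` still shared,
then fits a weighted line to `n` vs `L`: slope ≈ 1/m, x-intercept ≈ the
pre-translocated distance.  Its starts are seeded along the physically
meaningful manifold (choose a step-size and a pre-translocated distance,
derive `k_U` and all `n_i`), because incoherent starts stall in shallow
local optima of the `k_U`–`n` trade-off.

### Identifiability and uncertainty

With noise, `k_U` is sharply identified only when `k_end ≳ k_U` (the
last intermediate then tracks the arrival flux); when `k_end < k_U` the
objective develops a sloppy valley in which 2% noise can move the
*global* optimum ~15–20% along `k_U` — consistent with the ±12%
replicate scatter reported for this condition experimentally.  Parameter
spread across replicates (inverse-variance weighted mean ± sample sd,
`replicate_summary`) is the default uncertainty route.  A
residual-resampling percentile bootstrap is provided as an option; note
that the `m` estimator carries a noise-induced positive bias of the same
order as its sampling sd at 2% noise, so percentile intervals for `m`
are descriptive, not calibrated coverage statements (a per-trace free
baseline offset was tried as a remedy and rejected — it is collinear
with the saturating product term and degrades `m` recovery).

## Processivity algebra

`P = k_U/(k_U + k_d)` (per-step continuation; `k_d` is dissociation from
*intermediates*, deliberately distinct from `k_end`), `P = exp(−m/N)`
with `N` the processivity in amino acids, and the single-turnover peak
amplitude model `X̄ · Pⁿ · F`.  Conversions round-trip to 1e−12; `P = 1`
maps to a flagged domain error rather than infinite `N`.  Reported `P`
values use three decimals (two for the full-domain step) to match
conventional precision.

## Problem sizes

Closure (parameter-recovery) runs use the full default grids
(3 substrates × 2000 points) with 10 optimizer starts; test-suite
variants use 600–1500-point grids and 3–8 starts, which leave the
recovery accuracy unchanged on noiseless data.  The noisy-recovery and
bootstrap checks use 400–1000-point grids, 3 replicates and 60–100
resamples.

## Known limitations

* Strictly dark early intermediates; no partial signal before the last
  step, no intermediate dissociation inside the signal model.
* No reversible or heterogeneous steps; no dead-time correction.
* The excluded-length point estimate inherits the constant peak-offset
  bias of the model-independent intercepts.
* `k_U` weakly identified from noisy data when `k_end < k_U` (see
  above); the multimodality guard surfaces, rather than hides, this.
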
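# unfoldkin

Transient-state kinetic analysis of processive protein unfolding by
AAA+ motor proteins, from single-turnover stopped-flow fluorescence
time-courses.

ClpB-class disaggregases thread polypeptides through their axial channel,
unfolding folded domains as they go. In a single-turnover experiment the
motor is pre-bound to an engineered substrate — an unstructured binding
tract followed by 1–3 tandem titin I27 domains and a C-terminal dye —
and, after rapid mixing with ATP, the dye reports the motor's arrival by
protein-induced fluorescence enhancement (PIFE): the trace shows a lag,
a rise, and a decay. `unfoldkin` implements both analyses such data
support:

* **Model-independent (kinematic)**: substrate length vs. time of the
  fluorescence peak is a position–time plot; its slope is the overall
  unfolding rate (aa/s) and its intercept the pre-translocated distance
  `C`. Repeating at several pre-incubation delays `Δt1` and regressing
  the intercepts on `Δt1` yields the ATPγS-driven pre-translocation rate
  and the excluded length.
* **Model-dependent (global fit)**: all traces are fit simultaneously to
  an n-step sequential mechanism,

      F(t) = L⁻¹{ F₁·k_Uⁿ/((s+k_U)ⁿ(s+k_end))
               + F₂·k_end·k_Uⁿ/(s(s+k_U)ⁿ(s+k_end)) },   n = (L − C)/m,

  with the kinetic step-size `m` (aa/step) and unfolding rate constant
  `k_U` (s⁻¹) shared across substrates and `k_end`, `F₁`, `F₂` local.
  This deconvolves the overall rate `m·k_U` into step-size and stepping
  rate.
* **Processivity algebra**: `P = k_U/(k_U+k_d)`, `P = exp(−m/N)`, and
  the single-turnover peak-amplitude model `X̄·Pⁿ·F`.

A first-class synthetic-data module generates stopped-flow datasets with
the same statistical structure (baseline, labeling-efficiency amplitude
scaling, proportional Gaussian noise, delay-dependent pre-translocation),
so every analysis stage is validated by parameter-recovery closure.
See `docs/methods.md` for the model, numerics and design choices.

## Worked example

Simulate a three-delay, three-replicate dataset at the 1:1 ATP:ATPγS
condition (truth: `m` = 56.5 aa, `k_U` = 0.017 s⁻¹, excluded length
48 aa, ATPγS rate 0.09 aa/s, 2 % noise), run both analyses, and convert
the fitted step-size to a per-step processivity:

```python
import unfoldkin as uk

design = uk.condition_1to1(seed=7, noise_sd=0.02, n_replicates=3,
                           dt1_values=(300.0, 420.0, 600.0))
ds = uk.simulate_dataset(design)

res = uk.run_peaktime_pipeline(ds)
print(res.table())                      # per-delay kinematic fits

C = res.per_dt1[600.0].intercept        # pre-translocated distance at 600 s
traces = [uk.average_replicates([uk.relative_enhancement(tc)
                                 for tc in ds.select(substrate=s, dt1=600.0)])
          for s in ds.substrates]
fit = uk.fit_global(traces, C, seed=1, n_starts=10)
print(fit.m, fit.k_U, fit.mk_U)
print(uk.p_from_step_and_N(fit.m, 362.0))
```

Output (numbers printed by this exact script):

```
 dt1_s  slope_aa_per_s  slope_sd_aa_per_s  intercept_aa  intercept_sd_aa
 300.0        0.918547           0.013424     59.225333         4.027628
 420.0        0.909216           0.009399     75.014913         2.912850
 600.0        0.847218           0.034225     95.775456         4.834283
m = 61.0 aa, k_U = 0.0144 1/s, m*k_U = 0.88 aa/s
P = 0.845
```

Reading: the kinematic slopes (~0.85–0.92 aa/s) and the fitted overall
rate `m·k_U` = 0.88 aa/s agree, as they must if the peak marks arrival;
the 600-s intercept (~96 aa) is the distance already pre-translocated
during the ATPγS delay; and a ~60-aa step at a 362-aa run corresponds to
a per-step continuation probability of ~0.85. With 2 % noise the
individual estimates scatter around the generating values (56.5 aa,
0.017 s⁻¹) — averaging over replicates and delays, as
`replicate_summary` does, is how the headline numbers are obtained.

A `unfoldkin` command-line tool wraps the same stages
(`simulate`, `preprocess`, `peaktime`, `fit`, `processivity`,
`pipeline`); `unfoldkin pipeline --config cfg.yaml --out-dir out/` runs
everything end to end, reproducibly from the config seed.

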
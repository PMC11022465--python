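# strollpipe

From raw inertial gait signals to daily-life walking ability — a tested
pipeline for instrumented stroke-rehabilitation assessment.

People recovering from stroke are routinely assessed with a two-minute
walk test (2MWT), and gait speed from that test is used as a proxy for how
well they will walk in daily life. Wearable inertial measurement units
(IMUs) make much richer clinic measurements possible — stride timing,
trunk harmonics, signal complexity, left/right asymmetry — and also make
daily life itself measurable with a single body-worn accelerometer.
`strollpipe` implements the full computation chain needed to ask whether
that richer information adds anything beyond gait speed:

1. **`synthetic`** — generators for every input the pipeline consumes
   (walk-test signals, multi-day calf recordings, longitudinal cohorts),
   each with exact ground truth for parameter-recovery testing.
2. **`features`** — 2MWT processing: resampling to 100 Hz and gyroscope
   offset removal, foot-contact detection from the sagittal angular rate,
   and a 37-feature registry across four families (spatio-temporal,
   frequency, complexity, asymmetry).
3. **`daily`** — daily-life processing: 10-s epochs, gait/off-body
   classification, step counting, and per-epoch gait speed by
   zero-velocity-update (ZUPT) double integration of the
   anterior-posterior linear acceleration over swing phases; per-day
   summaries (steps, average and maximum speed, 8-h wear validity).
4. **`selection`** — |r| > 0.95 redundancy pruning, Kaiser-Meyer-Olkin
   sampling adequacy, z-scoring with stored parameters.
5. **`pca`** — correlation-matrix PCA with Kaiser (eigenvalue > 1)
   retention, component labelling, fixed-loading projection of external
   data, and the test-retest reliability panel: ICC(2,1) with F-based 95%
   CI, SEM, MDC = 1.96·√2·SEM, RMSE.
6. **`lmm`** — random-intercept mixed models per walking-ability outcome:
   a gait-speed-only baseline, collinearity screening (|r| ≥ 0.9), and
   forward selection of components as confounders (≥ 10% change in the
   gait-speed coefficient) or effect modifiers (interaction p < 0.05),
   compared via nRMSE / AIC / BIC with residual diagnostics.

The model at the core of stage 6 is, per outcome
(steps/day, average and maximum daily speed):

    y_ij = β₀ + β₁·speed_ij + Σ_k γ_k·PC_kij (+ δ_k·speed_ij·PC_kij) + b_i + ε_ij,
    b_i ~ N(0, τ²),  ε_ij ~ N(0, σ²)

with subject random intercepts `b_i` accounting for repeated sessions; a
PC enters only if it confounds or modifies the speed–outcome relation.

## Worked example

```python
import strollpipe as sp

# a clinic walk test: asymmetric gait at 0.8 m/s, stride time 1.2 s
truth = sp.GaitTruth(stride_time=1.2, gait_speed=0.8, asymmetry_ratio=1.2)
rec, events = sp.generate_2mwt_signals(truth, duration=120, rate=104, seed=7)
fv = sp.extract_features(rec)
print(f"gait speed  {fv['gait_speed']:.3f} m/s")
print(f"stride time {fv['stride_time_mean']:.3f} s")
print(f"step-time L/R ratio {fv['ratio_step_time']:.3f}")

# a day of free living walked at 1.0 m/s
tl = sp.make_daily_timeline(hours=9.0, gait_fraction=0.3, truth=sp.GaitTruth(
    stride_time=1.2, gait_speed=1.0), seed=1)
day_rec, day_truth = sp.generate_daily_recording(tl, noise_sd=0.3, seed=1)
summary = sp.process_daily_recording(day_rec)[0]
print(f"daily avg speed {summary.avg_speed:.3f} m/s, "
      f"steps {summary.steps} (truth {day_truth.steps}), valid={summary.valid}")
```

prints (seed 7 / seed 1):

```
gait speed  0.800 m/s
stride time 1.200 s
step-time L/R ratio 1.197
daily avg speed 1.006 m/s, steps 17571 (truth 17584), valid=True
```

i.e. the walk-test features recover the generated stride structure to the
sample level, and the daily chain recovers the true walking speed within
about 1% and the step count within 0.1% on this day.

The statistical stage runs the same way from a generated cohort:

```python
feats, outcomes, truth = sp.generate_cohort(sp.CohortSpec(seed=5))
pruned, report = sp.prune_correlated(feats[sp.synthetic.feature_columns(feats)])
z = sp.standardize(pruned)
model = sp.label_components(sp.fit_pca(z), z)
scores = sp.project(model, feats)
fit, trace = sp.forward_select(outcomes.join(scores), "avg_speed",
                               ["cov_confounder", "cov_modifier", "cov_null"])
print(trace.to_frame()[["candidate", "pct_change", "confounder",
                        "interaction_p", "modifier"]])
```

The trace shows the planted confounder flagged by the 10%-change rule and
the planted modifier by its interaction p-value, while the pure-noise
candidate is left out.

A thin CLI mirrors the chain
(`strollpipe simulate|features|daily|select|pca|lmm`, see `strollpipe --help`).

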
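# Methods

`strollpipe` implements an instrumented gait-assessment chain for stroke
rehabilitation: a two-minute walk test (2MWT) with inertial measurement
units (IMUs) on both feet and the low back yields a multi-family
gait-feature vector; a multi-day single calf-worn accelerometer yields
daily-life walking-ability measures (steps per day, average and maximum
daily gait speed); and a statistical stage — feature selection, principal
component analysis (PCA) and random-intercept linear mixed models — asks
whether walk-test gait information beyond gait speed improves the
estimation of daily-life walking ability. Because no clinical recordings
ship with the package, a synthetic-data module generates every input with
exact ground truth, which is what the test suite and the acceptance script
measure recovery against.

## Synthetic signal model

The generators aim for the *simplest* signals that expose every event and
feature the pipeline extracts, not biomechanical realism (explicitly a
non-goal; so are pathological gait phenotypes and magnetometer channels).

**Walk test.** Gait is a sequence of strides with mean stride time `T`
(default 1.2 s), per-stride durations Gaussian with coefficient of
variation `cv`, and stride length `L = v·T` at gait speed `v`. Asymmetry
enters as the left/right step-time ratio `a ≥ 1`: within a stride the left
step takes `a/(1+a)·T` and the right `1/(1+a)·T`. The sagittal foot
angular rate is a stance plateau at −0.15 rad/s plus a half-sine swing
peak (amplitude scaled to stride length), so a zero crossing brackets each
side of swing — the substrate of the event detector. The trunk oscillates
at step frequency (vertical, anterior-posterior) and stride frequency
(mediolateral) with a second harmonic; asymmetry adds odd harmonics, which
is what harmonic ratios respond to. Sensor frames use x = anterior,
y = left, z = up, with gravity +9.81 m/s² on z when upright. Two seconds
of quiet standing precede walking (as in a cone-to-cone protocol); the
gyroscope-offset estimator relies on such periods. White Gaussian noise
(default 0.05 m/s² on acceleration, 10% of that in rad/s on angular rate)
is added everywhere.

**Daily life.** An activity timeline of gait / sedentary / standing /
off-body bouts fills a single calf-sensor recording at 52 Hz,
acceleration-only by default (a gyroscope can be included to exercise the
fusion path). During each swing (half of the stride by default) the
anterior-posterior acceleration is one sinusoid period whose double
integral is exactly one stride length with zero velocity at both stance
anchors — the ground truth the ZUPT integrator must recover. The
acceleration-norm profile of each swing yields two band-limited peaks per
stride, i.e. one per step, which is what the norm-peak step counter
counts; the true step count is `floor(bout duration / step time)`.
Off-body bouts are exact zero-variance gravity so wear-time detection has
something detectable. One top-level seed fans out to per-stream child
seeds by stable hashing of stream names, so adding a stream never
perturbs existing ones.

**Cohort.** Each subject carries a latent "walking capacity" (SD 1.0
across 30 subjects by default, 3 sessions each, with per-session
variation of SD 0.5). The 2MWT gait speed is `0.7 + 0.25·capacity` m/s;
each named gait feature is `loading × capacity (+ minor-factor loadings)
+ noise` with a documented default loading panel (18 features, plus
asymmetry and variability minor factors). Outcomes follow
`outcome = α + β·speed + γ·z_conf + δ·(speed − 0.7)·z_mod + b_subject + ε`
with a planted confounder `z_conf = strength·capacity + 1.25·noise`
(outcome path `γ = 0.04·strength` on the average-speed scale), a planted
effect modifier with interaction coefficient `δ = 0.16·strength`, and a
pure-noise candidate. The strengths were fixed by design-time power
arithmetic so that, at the default cohort size, the 10%-change confounder
rule sits ≈4 SE above its threshold and the interaction Wald statistic
near 5 — i.e. the planted effects are meant to be found essentially
always, while the null candidate is flagged at roughly the nominal test
level. The interaction is generated on centered speed so that it adds as
little marginal outcome variance as possible.

## Pipeline stages and numerical choices

**Preprocessing.** All streams are linearly interpolated onto a uniform
100 Hz grid. The per-axis gyroscope offset is the median over stationary
samples (1-s windows with gyro-norm SD < 0.05 rad/s and acceleration-norm
deviation SD < 0.1 m/s²), falling back to the whole-recording median when
fewer than 1% of samples qualify.

**Gait events.** Mid-swing = sagittal angular-rate maxima (prominence
≥ 0.5 rad/s, minimum separation 0.4 s, both configurable); initial
contact = first zero crossing after mid-swing, final contact = last zero
crossing before it, both linearly interpolated between samples. Fewer
than four strides on either foot is an error, not a value. Strides longer
than 1.5× the median are flagged as turns (the 14-m path forces them) and
excluded from stride statistics; gait speed is walked distance over
elapsed time, with distance supplied directly or inferred from
(turn count + 1) path traversals.

**Feature families.** The registry carries 37 features: 13
spatio-temporal, 12 frequency (per trunk axis: Welch dominant frequency
and peak power in 0.3–5 Hz, index of harmonicity = power at the dominant
frequency over the summed power of its first six harmonics, and harmonic
ratios over the first 20 stride harmonics — even/odd for
anterior-posterior and vertical, odd/even for mediolateral — computed on
exact DFT bins of the signal cropped to whole strides), 6 complexity
(sample entropy with m = 2, r = 0.2·SD on a 30-s 100 Hz window to bound
the O(n²) pair count; step/stride regularity as unbiased, lag-0-normalized
autocorrelation peaks, and their ratio), and 6 asymmetry (symmetry index
`|L−R| / (0.5(L+R)) × 100%` and max/min ratios for step, stance and swing
time). The full supplementary catalogs of commercial pipelines run to a
hundred-plus features; the registry pattern admits additions without API
change. Degenerate inputs (constant axes) raise errors naming the
affected features rather than emitting silent numbers.

**Daily life.** Recordings are cut into non-overlapping 10-s epochs
(trailing remainder dropped). The default rule-based classifier labels an
epoch *gait* when the 0.5–3 Hz fraction of the detrended acceleration-norm
power exceeds 0.35 and the norm SD exceeds 0.4 m/s², *off-body* when the
norm SD stays below 0.01 m/s², else *non-gait*; it replaces the trained
neural network of production systems behind the same single-function
contract, and anything honoring that contract can be substituted. Steps
are peaks of the 0.5–3 Hz band-passed norm (4th-order Butterworth,
zero-phase) with a 1 m/s² prominence floor, a 0.25 s minimum separation,
and a relative gate at 0.3× the 95th-percentile prominence that rejects
filter ripple; consecutive gait epochs are counted on their concatenated
signal so boundary steps survive. Gravity is removed per epoch by 0.25 Hz
low-pass (acceleration-only) or by a gravity-tracking complementary
filter (gain 0.02) when angular rate exists; the anterior-posterior axis
is the first principal horizontal component of the residual. Stance is
where the detection statistic — smoothed angular-rate norm, or the 0.15-s
rolling SD of the acceleration-norm deviation when no gyroscope exists —
stays below threshold (0.5 rad/s / 1.0 m/s²) for ≥ 0.08 s; stance and
swing tile each epoch exactly. Velocity restarts from zero at each stance
(the zero-velocity update); per interior swing the linear velocity trend
is forced to zero at both anchors before integrating to displacement,
and epoch-edge partial swings are integrated one-sidedly from their
single anchor without detrending. Epoch speed is the summed absolute
displacement over 10 s. Per calendar day (midnight boundaries from the
recording's clock offset): wear time = 10 s × non-off-body epochs, valid
iff ≥ 8 h; gait epochs at or below 0.05 m/s are excluded; average speed
is the mean of the rest and "maximum" speed the 95th percentile by
default (the literal maximum of a single 10-s double integration is
noise-dominated; `max_speed_stat="max"` restores it), clamped to at
least the average.

**Selection, PCA, reliability.** Redundancy pruning is iterative: while
any |r| > 0.95 pair exists, the member with the highest summed absolute
correlation to all current features is dropped and the matrix recomputed;
absolute correlation is used (sign-agnostic redundancy) and ties break by
column order. KMO comes from the anti-image: with `S = R⁻¹`, partial
correlations `p_jk = −S_jk/√(S_jj S_kk)` and
`KMO_j = Σr²_jk / (Σr²_jk + Σp²_jk)`; a 1e-8 ridge is recorded when `R`
is singular, under-determined tables (rows < features) are flagged, and
0/0 denominators yield a degeneracy flag instead of a number.
Standardization is the column z-score with the n−1 SD; the fitting
means/SDs are stored and reused verbatim when projecting external data
(the alternative — re-estimating moments on the external table — is a
flag, `refit_standardization`). PCA is the eigendecomposition of the
correlation matrix (identical to the covariance of z-scores — stated to
remove ambiguity); components with eigenvalue > 1 are retained (Kaiser),
any eigenvalue in [0.95, 1.05] sets a near-threshold flag, each retained
loading column is oriented so its largest-magnitude entry is positive,
and components are labelled by the feature with the highest
|score–feature correlation| (ties by column order, recorded). Test-retest
reliability per component: ICC(2,1) from the two-way ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with k = 2, F-based
95% confidence bounds (deterministic, no resampling), SEM = pooled
session SD × √(1 − ICC), MDC = 1.96·√2·SEM, test-retest RMSE, and the
qualitative bands (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9
excellent).

**Mixed models.** Each outcome gets
`outcome ~ speed (+ candidates) + (1 | subject)`. Estimates and their
Wald CIs come from REML fits (BFGS with Powell/Nelder-Mead fallbacks —
the L-BFGS path in the underlying optimizer fails on these designs);
AIC/BIC always come from maximum-likelihood refits because REML
likelihoods are not comparable across fixed-effect structures, with
`k = fixed effects + 2` variance parameters. nRMSE is the RMS residual
over the observed outcome range (a mean normalizer is the configurable
alternative); residuals are conditional on the predicted random effects,
falling back to marginal residuals at variance boundaries. Candidate
screening drops any component with |r| ≥ 0.9 against gait speed or an
earlier candidate (gait speed itself is never dropped). Forward selection
visits candidates in descending explained-variance order (order is a
parameter): a candidate is a confounder when adding its main effect
moves the gait-speed coefficient by ≥ 10% relative to the gait-speed-only
model — judged with the candidate alone against the base model by
default; `reference="sequential"` instead stacks candidates on the
working model — and an effect modifier when the speed × candidate
interaction is significant at 0.05 by a Wald test against a t reference
with residual degrees of freedom (the normal reference is measurably
anti-conservative at these sample sizes). Retained candidates accumulate
into the definitive model, which always contains gait speed;
non-convergence on a candidate is recorded as indeterminate and skipped.
Diagnostics report residual skewness, excess kurtosis, the
D'Agostino-Pearson normality test, and the slope of |residual| against
fitted values as a heteroscedasticity screen.

## What the synthetic data does and does not show

The generators share exact, simple structure: noiseless periodicity with
known events, rank-controlled feature tables, Gaussian noise, and linear
outcome models. Passing tests therefore demonstrate that the *pipeline*
is correct — events, integration, KMO/PCA/ICC arithmetic, and the
selection logic recover what was planted at the stated rates — not that
the defaults are tuned for hemiparetic gait, turning-rich home
environments, soft-tissue artifact, or sensor drift. In particular the
rule-based activity classifier is validated only against the generator's
clearly separated activity classes, and the daily speed estimator
inherits a small positive bias (~2–3%) from one-sided edge-swing
integration that real, less stereotyped gait would trade against other
error sources. The cohort's planted-effect strengths are deliberately
strong; they measure the selection procedure's behavior at a documented
operating point, not the effect sizes of any clinical population. One
caveat worth knowing: when a strong interaction truly drives an outcome
but is not in the model, interaction tests of *other* candidates become
anti-conservative — the specificity of the selection procedure is
therefore measured on cohorts generated without a planted interaction.

## Problem sizes

Defaults were chosen so every check runs comfortably on a laptop core:
2-minute walk tests at 104 Hz, nine-hour daily recordings at 52 Hz,
cohorts of 30 subjects × 3 sessions, 100-replicate Monte-Carlo runs for
selection calibration, and 50 random tables for oracle-equivalence
checks. Sample entropy uses a 30-s window; all other features use full
recordings.
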
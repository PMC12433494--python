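# Methods

This note documents the models implemented in `idoct`, the assumptions
behind them, the synthetic cohorts used to validate them, and the
numerical and design choices that were genuinely open.

## The decomposition model

Self-administered digital cognitive tasks record, per trial, a condition
label, a correctness flag and a reaction time (RT). The package's core
model splits each RT into a cognitive **Answer Time** (AT) and a
participant-level **Response Delay Time** (DT),

    RT = AT(condition) + DT,

where DT collects hand-motor and device latency, and summarises each
participant-task-session with a **Cognitive Index** AS in [0, 1] that
triangulates accuracy, answer speed and trial difficulty.

### Calibration on a normative cohort

All difficulty and timing references are estimated once, on a large
neurologically healthy cohort, and then frozen:

1. **Speed score.** `s = clip((rt_ceiling − rt) / (rt_ceiling − rt_floor), 0, 1)`,
   with floor/ceiling the 5th/95th percentiles of the normative RTs for
   the task.
2. **Trial performance.** `p = accuracy · (w + (1 − w)·s)` with `w = 0.5`:
   a correct-but-slow response scores at least `w`, a fast correct
   response up to 1, an incorrect response 0.
3. **Raw difficulty.** `D_raw(c) = 1 − mean(p)` over normative trials with
   condition label `c`.
4. **Ability-scaled difficulty.** Provisional abilities
   `A_i = Σ p·D′ / Σ D′` over participant i's trials, and
   `D′(c) = clip(D_raw(c) + mean(A | attempted c) − mean(A), 0, 1)`,
   iterated to a fixed point (tolerance 1e−4). The correction removes the
   bias that arises when only stronger participants reach harder
   conditions (progressive designs).
5. **AT curve and DT.** Alternation between a condition-level answer-time
   curve — the isotonic (monotone in `D′`) regression of the per-condition
   medians of `rt − DT_i` — and per-participant delays
   `DT_i = max(0, mean(rt − AT_c))`.

The frozen table per task carries `D_raw`, `D_scaled`, the AT curve, the
RT percentiles, and the normative mean DT.

**Identifiability.** `RT = AT + DT` admits an additive shift: any constant
can move between the AT level and all delays. Worse, the median-based AT
step and the mean-based DT step disagree under right-skewed RT noise, so
the literal alternation transfers the (mean − median) of the noise from AT
into DT on every pass and never settles. The model therefore fixes the
gauge at each iteration: delays are re-anchored so that the 1st percentile
of the normative DT distribution is zero (the fastest responders in the
reference cohort define zero delay), then floored at zero. With the gauge
fixed, the alternation converges in a handful of iterations.

### Applying the model

For new data the AT curve stays frozen: a session's delay is
`DT = max(0, mean(rt − AT_c))` in a single step, per-trial answer times
are `rt − DT`, and

    AS = Σ accuracy · D′(c) · (w + (1 − w)·s*) / Σ D′(c)

over the session's usable trials, where `s*` is the speed score of the
answer times against the frozen percentiles shifted by the normative mean
DT.

**Censoring.** Trials without a registered response (response-window
timeouts, dropped taps) are censored: the recorded RT is the window, not
AT + DT, and the intended response is unknown. They are excluded from
delay estimation and from the Cognitive Index sums; sessions with fewer
than half of their trials usable are treated as failed administrations and
dropped. The *standard* accuracy metric counts the same trials as errors —
deliberately, since "number correct" is exactly how conventional scoring
treats a missed response. This asymmetry is the mechanism by which motor
impairment confounds conventional scores while leaving the modelled index
clean; it mirrors how motorically impaired users actually lose trials
(slow or unregistered responses) rather than producing wrong answers.
The exception is a pure tap-precision task, where mis-taps genuinely score
as errors and the index legitimately reflects hand function.

DT is computed per task (the unit at which confound results are reported),
not pooled across the battery; pooling would under-remove the delay in
high-motor-demand tasks, whose impairment penalty exceeds the battery
average.

## Global factor (Bayesian PCA)

Per recovery phase (acute ≤ 14 d < subacute ≤ 180 d < chronic) and per
metric family (Cognitive Index; standard accuracy counts), the participant
× task matrix is summarised by the first principal axis of a probabilistic
PCA fitted by EM directly on the incomplete matrix; with flat priors the
estimate coincides with maximum-likelihood PCA, and posterior means impute
the missing cells. Initialisation is classical PCA of the mean-imputed
matrix, so fits are deterministic without a seed. Variance explained is
computed on the standardized pairwise-complete covariance
(`uᵀSu / trace S` for the unit first axis `u`). If a participant has
several sessions inside one phase, the session closest to the phase's
median day is used. Loadings are sign-fixed so the mean loading is
positive. Phases with fewer than 10 rows are refused rather than fitted.

## Regression machinery

All patient models share the fixed-effects structure
Age + Age² + Gender + Education (reference: lowest level) + English
proficiency + log(1 + NIHSS) + time since stroke, with subject random
intercepts and random time slopes. Continuous covariates are z-scored on
the analysis table; NIHSS is log(1 + x)-transformed and never
standardised (its range includes 0); time enters as z-scored log(1 + days),
matching the logarithmic shape of post-stroke recovery.

* **Gaussian outcomes** (Cognitive Index, Response Delay Time, median RT)
  are Yeo-Johnson transformed (maximum-likelihood λ) and standardised, so
  estimates are standardised betas. Fits use REML; a singular
  random-slope fit falls back to a random intercept and is flagged.
  Residual normality (Shapiro) is attached to every fit.
* **Accuracy counts** are aggregated binomial mixed models with the same
  structure, fitted by a Laplace approximation (the approximation `glmer`
  uses at default settings); a cross-check against `glmer` on simulated
  data agrees to ~3 decimals in estimates and SEs. Because task-session
  level ability fluctuations create extra-binomial variation, SEs carry a
  quasi-likelihood dispersion correction from conditional Pearson
  residuals; this costs power but keeps the null rejection rate at its
  nominal level (verified by simulation).
* **Multiplicity.** Benjamini-Hochberg q-values are computed for two
  families: the four metrics within each task, and the tasks within each
  metric. The *confounded* verdict uses the across-task family; both are
  reported.
* **Criterion validity** regresses the clinical criterion on G by OLS per
  phase and family; p-values are deliberately uncorrected.

## Canonical correlation analysis

Per phase (subacute, chronic), the per-task Cognitive Indices are related
to log-transformed lesion and white-matter-hyperintensity volumes of the
imaging subcohort. Both blocks are standardised; weights come from the
SVD of the doubly whitened cross-covariance (numerically equal to the
generalized-eigenproblem closed form); variates have unit variance, and
each variate is sign-fixed so its largest-loading variable loads
positively. Inference permutes the imaging rows (default 10,000 draws;
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)` per mode, re-estimating each
mode's correlation per draw). Missing task entries would leave almost no
complete rows at 18 columns, so the pipeline imputes them with the EM-PCA
posterior means (participants with at least half the battery observed);
the CCA itself applies listwise deletion to whatever it receives.

## The synthetic cohorts

No real cohort ships with the package; the generator produces data with
the statistical structure the analysis assumes, with ground truth stored
in a separate `truth.csv` that estimation code never reads.

**Participants.** Demographic and clinical marginals are anchored to a
large normative cohort (age 60.8 ± 10.1, range 40-95) and a stroke cohort
of the scale typically reported in digital-assessment validation studies
(age 63.01 ± 14.1 range 24-97; NIHSS mean 4.93, SD 4.66, range 0-26;
impaired responding hand in ~27.5%; English as second language 34.5%;
education in four ordinal bands; sessions at ~4, ~94 and ~371 days with
attendance 77%/42%/77%; concurrent imaging in 46%). Latent ability is
built additively from age (negative, with a small quadratic), education
(positive, linear in the 1-4 ordinal), second-language status and
log(1 + NIHSS) (negative), plus N(0, 0.55²) individual variation, and
recovers along a subject-specific random slope on log(1 + days). A latent
response-caution trait trades accuracy for speed with a small weight.
MoCA-like (0-30) and IADL-like (0-8) criteria are noisy increasing affine
functions of ability (MoCA noise SD 0.6 — a high-fidelity
clinician-administered criterion); lesion and WMH volumes are lognormal
with negative ability slopes, and in the chronic phase high WMH burden
additionally depresses attention/speed/memory task performance (the
structure the CCA back-projections are asked to recover).

**Trials.** Accuracy follows a one-parameter item-response model,
`P(correct) = sigmoid(1.5·(θ + 0.1·caution − b_c))`, with condition
difficulties `b_c` strictly increasing within task. Answer time is a
fixed encoding share (45% of the task's base time) plus a
difficulty-graded operation share scaled by `exp(−η·θ + 0.05·caution)`
(η = 0.12 for high-cognitive-demand tasks, 0.05 otherwise); motor delay is
lognormal (median 300 ms, σ = 0.5) plus, for impaired users, a
severity-scaled addition (mean 200 ms, boosted ×2.2 in high-motor-demand
tasks); additive RT noise is lognormal (median 180 ms, σ = 0.75). RTs
beyond the response window are timeouts (accuracy 0, RT clamped).
Splitting the ability effect into the operation share keeps person-level
cognitive RT spread modest relative to motor spread — the regime in which
a per-session mean-residual delay estimate is interpretable as motor
delay.

**Motor impairment harms accuracy only through the response channel**:
no-response mis-taps ("fumbles", rate 0.22 scaled by severity, high-motor
tasks only) and timeouts; wrong-answer slips (rate 0.18) occur only in the
pure tap-precision task, whose score is hand function by design. Latent
ability is never touched — this is exactly the confound the decomposition
is supposed to remove, so the generator keeps it strictly separable.

**Task battery.** 18 tasks tagged by domain and by motor/cognitive
demand: 7 high-motor (precision tapping, choice reaction, symbol
matching, trail making, spatial span, target cancellation, figure
copying) and 6 with near-ceiling "screening" difficulty. The
high-motor visuomotor tasks use near-ceiling accuracy grades — as in real
trail/cancellation/copying designs, failing slow rather than wrong — which
concentrates their conventional scores' information in exactly the channel
that motor impairment corrupts. A progressive-termination option (task
ends after 3 consecutive failures) exists in the generator but is off in
the default registry: an attempted-trials-weighted index is upward-biased
for early stoppers, so termination designs need a different scoring rule.

**What the generator does not emulate.** Real stimulus content and
response interfaces; device heterogeneity beyond a scalar delay;
practice/fatigue effects; non-monotone recovery; dropout that depends on
outcome; voxelwise imaging. Passing tests show the estimators recover the
structure *this* generator plants at realistic sizes and noise levels —
not that the same holds for any particular real battery.

## Benchmark and scaled problem sizes

The packaged benchmark uses seed 1, 400 normative + 200 patients, all 18
tasks (~40 trials each, ~700k trials total), and 999 CCA permutations.
Replicated studies run at sizes chosen to keep the full validation suite
comfortably re-runnable on a single CPU: the null-generator confound
calibration uses 50 replicate patient cohorts (n = 110) on a 3-task
battery against one fixed normative calibration; the mixed-model type-I
study uses 150 replicates of 250 subjects × 3 sessions, pooling all null
fixed effects (1,500 tests); the permutation-uniformity study uses 50
replicates with 199 permutations each. On this benchmark the estimated
delay correlates with the true per-task motor delay at r ≈ 0.96, every
task's scaled difficulty ranks the true condition difficulties at
ρ ≥ 0.98, the impaired-hand term is significant for standard metrics in
every high-motor task and for the Cognitive Index only in the
tap-precision task, and the Cognitive Index G explains more MoCA-like
criterion variance than the accuracy G in all three phases.

## Numerical choices and degenerate inputs

* Convergence tolerance 1e−4 for the difficulty and AT/DT fixed points and
  for the EM-PCA (the one tolerance used throughout).
* Implausible-RT cleaning removes non-timeout trials outside
  [200 ms, response window]; 200 ms is a standard physiological floor.
  Timeout rows are kept (their RT is the window by construction).
* Unseen condition labels at decomposition time are hard errors — silent
  imputation would corrupt the difficulty weighting.
* Sessions with fewer than 3 usable trials are decomposed but flagged
  `low_confidence`; sessions below 50% usable are dropped.
* The Yeo-Johnson branches are evaluated with `expm1`/`log1p` forms, so
  forward and inverse are stable through λ = 0 and λ = 2 and round-trip to
  1e−10.
* MixedLM occasionally steps into a singular random-effects covariance
  under L-BFGS; the fit retries with the default optimizer, then falls
  back to a random intercept if the slope variance is degenerate.
* CCA refuses rank-deficient blocks (no silent regularization) and
  requires n > p + q complete rows.
* Wald confidence intervals throughout (swap-in point for profile or
  bootstrap intervals).

## Known limitations

* The decomposition absorbs *all* person-level mean RT differences within
  a task-session into DT; slowing of cognitive origin is indistinguishable
  from motor delay at that level, so DT is interpretable as motor/device
  delay only when motor variation dominates — and, conversely, the index's
  speed term mostly reflects within-session structure.
* A uniform accuracy deficit caused purely by motor impairment (e.g. a
  wrong-answer mis-tap rate in a non-motor task) cannot be removed by any
  trial-level reweighting; the pure-motor task demonstrates the behaviour.
* The aggregated binomial model's dispersion correction is conservative
  when overdispersion is mild.
* The quasi-Bayesian PCA uses flat priors; with very few rows per phase
  the factor is unstable, hence the 10-row refusal.
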
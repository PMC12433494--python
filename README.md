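# idoct — separating cognitive ability from hand-motor impairment in digital cognitive tests

Self-administered digital cognitive tasks confound two things: how well a
person *thinks* and how well their responding hand *moves*. In
neurological populations (stroke, Parkinson's disease, multiple
sclerosis, traumatic brain injury) both are impaired at once, so
conventional outcome measures — number of correct responses, median
reaction time — systematically overstate cognitive deficits in people
with hand-motor impairment.

`idoct` implements an iterative decomposition of trial-level task data
(IDoCT: **I**terative **D**ecomposition **o**f **C**ognitive **T**asks)
that separates the two, together with the full validation pipeline a
study of such a method needs, exercised end-to-end on synthetic cohorts
with known ground truth.

## The model

Each reaction time is split into a cognitive **Answer Time** and a
participant-level **Response Delay Time**,

    RT = AT(condition) + DT,

where the condition-level AT curve is calibrated on a large normative
cohort (monotone in ability-scaled condition difficulty *D′*) and frozen.
Per participant-task-session the model reports

* `delay_time` — `DT = max(0, mean(rt − AT_c))`, the non-cognitive
  response latency (motor, device);
* `cognitive_index` — an ability score in [0, 1],

      AS = Σ accuracy · D′(c) · (w + (1 − w) · s*) / Σ D′(c),

  triangulating accuracy, answer speed (`s*`, the speed score of the
  answer times) and trial difficulty, with `w = 0.5`.

Condition difficulties are estimated from normative group performance
`p = accuracy · (w + (1 − w) · s)` and corrected for ability-dependent
progression (`D′(c) = clip(D_raw(c) + mean ability of attempters − grand
mean, 0, 1)`), iterated to a fixed point. Trials without a registered
response are censored rather than scored as errors — the key difference
from conventional accuracy counts, which is exactly where the motor
confound lives. See `docs/methods.md` for the full account.

Around the decomposition the package provides, as
statsmodels-style model/results objects:

| Component | What it does |
|---|---|
| `cohort` | synthetic normative + longitudinal patient cohorts with latent ability, motor delay, mis-taps, timeouts, criterion scores and imaging burden (ground truth in a separate `truth.csv`) |
| `IDoCTModel` / `IDoCTResults` | normative calibration; decomposition of new sessions |
| `BayesianPCA`, `extract_g` | EM principal axis over the participant × task matrix under missingness → global cognition factor G per recovery phase and metric family |
| `fit_lmm`, `fit_binomial_glmm`, `hand_impairment_analysis` | Yeo-Johnson + Gaussian mixed models and aggregated binomial mixed models (random intercept + time slope) with BH-FDR over both test families |
| `criterion_validity` | OLS of MoCA-like / IADL-like criteria on G |
| `CCA`, `permutation_test` | canonical correlation of per-task indices vs imaging burden with permutation inference and back-projected loadings |
| `run_pipeline` / `idoct` CLI | the whole analysis behind one config |

## Worked example

```python
import idoct

# a small synthetic cohort: 120 normative + 60 patients, 18 tasks
participants, trials, registry = idoct.benchmark_cohort(
    seed=7, n_normative=120, n_patient=60)

windows = {t.task_id: t.response_window for t in registry}
kept, report = idoct.clean_trials(trials, rt_min=200, rt_max=windows)

norm = kept[kept.participant_id.str.startswith("n")]
calib = idoct.IDoCTModel(norm).fit()          # normative calibration
decomp = calib.decompose(kept[kept.participant_id.str.startswith("p")])

print(calib.summary().head(3)[["task_id", "condition_label", "d_scaled", "at_ms"]])
print(decomp.head(3)[["participant_id", "task_id", "cognitive_index", "delay_time"]])
```

```
      task_id condition_label  d_scaled        at_ms
0  arithmetic             c01  0.221096  1165.274847
1  arithmetic             c02  0.360871  1247.966940
2  arithmetic             c03  0.494692  1313.665123
  participant_id          task_id  cognitive_index  delay_time
0          p0001       arithmetic         0.163720  614.305641
1          p0001       arithmetic         0.177019  598.959574
2          p0001  choice_reaction         0.712724  518.149953
```

`d_scaled` grades the task's conditions from easy to hard on the
normative cohort; `at_ms` is the frozen cognitive answer-time curve.
Each patient session then gets a `cognitive_index` (ability on a 0–1
scale, higher = better) and a `delay_time` in milliseconds — the motor /
device latency that has been removed from the cognitive score.

The full analysis — global factors per recovery phase, the impaired-hand
confound regressions, criterion validity and the imaging CCA — runs from
the command line:

```bash
idoct all --seed 1 --out results/
```

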
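# repdyn — repetition dynamics of visual gamma-band activity

When the visual system sees the same stimulus repeatedly, narrowband
gamma-band activity (~30–90 Hz) in early visual cortex does not simply
adapt away: it drops steeply over the first ~10 presentations, then climbs
steadily across further repetitions, and part of the gain persists even
after minutes of other stimuli. `repdyn` is a tested, reusable
implementation of the analysis chain behind this phenomenon, aimed at
researchers analyzing source-level M/EEG from blocked repetition designs —
or stress-testing such analyses on synthetic data with known ground truth.

The package covers:

* **Synthetic experiments** (`repdyn.synth`) — blocked sessions (ABCDA2,
  120 trials/block, 30 subjects) with repetition-modulated gamma bursts on
  a 1/f background, evoked transients, pupil light-reflex traces,
  microsaccade-laden gaze traces, coupled VAR source pairs with an analytic
  spectral Granger-causality (GC) oracle, and behavioral responses; all
  ground truth exposed.
* **Spectral estimation** (`repdyn.spectral`) — dual-band Hann/Slepian
  multitaper power, per-trial stimulus/baseline change spectra,
  time-frequency maps, evoked-component magnitudes.
* **Gamma peaks** (`repdyn.peakfit`) — semilog 1/f removal, Gaussian band
  peaks with cohort fallbacks, and the per-trial gamma peak-frequency
  estimator.
* **Trajectories** (`repdyn.trajectory`) — cohort averaging, broken-line
  breakpoint search, and the exponential-plus-linear model
  y = a·e^(−x/τ) + b·x + c.
* **Hierarchical regression** (`repdyn.lmm`) — `CrossedLMM`, a REML
  estimator with crossed subject/orientation random intercepts,
  Satterthwaite p-values, subject-level bootstrap CIs, and the
  dual-significance gate (both must agree); validated against R's lmerTest.
* **Connectivity** (`repdyn.connectivity`) — Wilson spectral matrix
  factorization, Geweke spectral GC, early/late repetition contrasts with
  cluster and t_max permutation statistics, time-reversal validation, and
  the gamma-power confound control.
* **Eye signals** (`repdyn.eyes`) — pupil preprocessing with MAD-based
  outlier interpolation and the constriction metric; Engbert–Kliegl
  microsaccade detection.
* **Orchestration** (`repdyn.pipeline`, `repdyn.cli`) — a seeded
  simulate → fit → report pipeline and a thin `repdyn` command-line
  interface, plus readers for external per-trial tables via column-name
  mapping.

## Worked example

Simulate a full cohort at the default study conditions and fit the
hierarchical regression for induced gamma power:

```python
from repdyn import synth, lmm

table = synth.generate_trial_table(synth.ExperimentConfig(seed=11))
res = lmm.fit_lmm(table, response="gamma_power", n_boot=200, seed=7)
print(res.summary())
```

```
Crossed random-intercept LMM (REML)
n_obs = 18000   converged = True   singular = False
var(subject) = 749.5   var(orientation) = 43.14   var(residual) = 1.206e+04

                       coef        se       t         df  p_satterthwaite    ci_lo    ci_hi  dual_significant
intercept             81.02     8.706   9.307      85.83        1.187e-14    64.56    97.46              True
repetition           0.3809   0.02682    14.2  1.796e+04        1.534e-45    0.325   0.4473              True
trial               0.06802  0.006851   9.929  1.796e+04        3.586e-23  0.05639  0.08059              True
repetition_block      7.206     2.906    2.48  1.795e+04          0.01316    1.908    12.83              True
iti_s                 1.578     1.377   1.146  1.796e+04            0.252  -0.1065     3.19             False
ms_rate               1.244      1.38  0.9016  1.796e+04           0.3673     -1.3    3.823             False
pupil_constriction  -0.3596    0.6513 -0.5521  1.796e+04           0.5809   -1.667   0.7101             False
early_repetition     -2.835    0.6024  -4.706  1.796e+04        2.539e-06   -4.134   -1.742              True
```

Reading the table: gamma power rises 0.38 pp per repetition of the same
stimulus (the steady increase) and 0.068 pp per trial regardless of
stimulus; the repeat block sits 7.2 pp above what the other regressors
predict (persistence); and the early-repetition ramp contributes a drop of
−9 × (−2.835) ≈ 25.5 pp over the first ten presentations in this cohort.
A coefficient is flagged `dual_significant` only when the Satterthwaite
p-value is below 0.05 and the bootstrap 95% CI excludes zero.

Fitting the cohort repetition trajectory of the same table:

```python
from repdyn import trajectory as traj

reps, series = traj.subject_average_trajectory(table, "gamma_power")
fit = traj.exp_linear_fit(series, x=reps.astype(float) - 1)
smooth = traj.running_average(series, traj.smoothing_width(len(series)))
print(fit.tau, traj.broken_line_fit(smooth).breakpoint)
```

gives `tau = 4.02` repetitions (generating value 3.5) with adjusted
R² = 0.59 and a broken-line breakpoint at repetition 13 for this seed.

The same stages run from the shell:

```bash
repdyn simulate --seed 11 --out trials.tsv
repdyn trajectory trials.tsv --measure gamma_power
repdyn lmm trials.tsv --response gamma_power --boot 200 --seed 7
repdyn run --seed 3 --out-dir results_run
```

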
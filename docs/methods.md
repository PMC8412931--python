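# Methods

`repdyn` models how narrowband gamma activity (~30–90 Hz) in early visual
cortex changes when the same stimulus is shown over and over: a fast drop
across the first ~10 presentations riding on a slow, steady increase across
all 120 presentations of a block, with partial persistence when the first
block's stimulus returns after intervening blocks. The package implements
the full analysis chain — per-trial spectral estimation, gamma peak
extraction, trajectory models, a hierarchical regression with a
dual-significance rule, nonparametric spectral Granger causality with
time-reversal validation, and pupil/microsaccade covariate processing —
together with a synthetic-experiment generator whose ground truth makes
every stage testable for parameter recovery.

## The synthetic experiment

A session is 30 subjects × 5 blocks (A B C D A2, the last repeating block
A's grating orientation) × 120 trials, each trial a 1 s gray-screen
baseline followed by 0.3–2 s of grating stimulation (truncated-Cauchy
duration, x0 = 1.65 s, FWHM = 0.2 s). Two tiers of synthesis exist:

* **Measure level** (`generate_trial_table`): per-trial gamma power (in
  percentage points of induced change), gamma peak frequency, pupil
  constriction, ERF component magnitudes, reaction time and accuracy, each
  as ground-truth trajectory plus noise. This is the workhorse for the
  regression and trajectory stages.
* **Time-series level** (`generate_experiment`): source-level traces at
  1200 Hz containing a 1/f^χ background (χ = 2), an amplitude-modulated
  narrowband gamma burst present only post-stimulus (filtered-noise
  carrier, 10 Hz FWHM, so spectral peaks have realistic width; per-trial
  power normalized to the configured trajectory — a Hilbert-envelope oracle
  confirms agreement within 2% at zero background), evoked transients at 60
  and 120 ms, and optional 50 Hz line noise.

The gamma-power trajectory is y(r, t) = a·e^(−(r−1)/τ) + b·(r−1) + c +
trial_slope·(t−1) + a2_boost·1[A2], with r the within-block repetition and
t the session trial number. Defaults encode the study conditions: τ = 3.5
repetitions, b = 0.40 pp/repetition, trial_slope = 0.07 pp/trial,
a2_boost = 7.8 pp, and a = 39.2 pp, chosen so that the regression readout
of the drop over the first ten presentations equals 30.8 pp. Peak frequency
rises 0.05 Hz/repetition, falls 0.01 Hz/trial, and gains 3.2 Hz in the
repeat block from a base of 52 Hz. Pupil constriction decays with its own
τ = 5.6 repetitions from 1.4 to 0.8 z-units. Reaction times are
shifted-lognormal around a deterministic trend (overall mean ≈ 484 ms,
15 ms early speed-up, +0.1 ms/repetition, −0.07 ms/trial, +12 ms in A2);
accuracy is Bernoulli at 0.69.

Noise scales are calibrated to the reported quality of the cohort
trajectory fits: per-trial gamma noise of 110 pp and pupil noise of 1.25 z
yield adjusted R² ≈ 0.68 and ≈ 0.36 for the exponential-plus-linear cohort
fits. Between-subject structure: random intercepts (30 pp subject,
5 pp orientation) and a ±30% spread of the early-decay amplitudes, coupled
across gamma and pupil at ρ = 0.45.

**What the generator does not emulate.** Trial-to-trial noise is white;
real single-trial gamma estimates share slow within-subject state
fluctuations. One consequence is deliberate and documented: with white
noise at the calibrated level, per-subject early-slope estimates are so
variable (SE ≈ 5× the between-subject spread) that the across-subject
gamma–pupil slope correlation observed in synthetic cohorts is attenuated
to near zero even though the generating correlation is 0.45; the three
quantities (cohort R², per-trial CI widths, slope correlation) are not
jointly reproducible under white noise. The generator also omits sensor
forward models, head geometry, eye blinks, and artifact structure; passing
tests therefore validate the estimators, not robustness to MEG artifacts.

## Spectral estimation

Power uses a dual-band scheme: ≤20 Hz from 0.5 s Hann windows (2 Hz
resolution), >20 Hz from 1/3 s windows with three Slepian tapers; all
windows overlap 50%, are demeaned and linearly detrended, and are
zero-padded to 1 s, putting both bands on a common 1 Hz grid. Tapers are
unit-energy and the one-sided spectrum sums to the windowed variance
(Parseval). Three well-concentrated tapers on a 1/3 s window imply a
time-half-bandwidth of 2, i.e. ±6 Hz spectral concentration; the sometimes
quoted ±3 Hz corresponds to the Rayleigh resolution of the window, not the
multitaper main lobe, and the half-power-width test asserts against the
taper-transform oracle instead. Induced change is per-trial stimulation
power (0.3–1.3 s) divided by the block-mean baseline power (−1–0 s) of the
same subject; percentage points are (ratio − 1)·100. Consecutive windows
start at the epoch start and a final partial window is dropped.
Time-frequency maps reuse the scheme with 4 s padding (0.25 Hz grid) and
per-sample window centers; centers whose window leaves the epoch are NaN.
ERFs are low-passed with an acausal Gaussian kernel (−6 dB at 80 Hz,
σ_t = √(ln 2 / 2)/(π·80) ≈ 2.34 ms), baselined, and summarized per trial as
the mean absolute deflection in the C1 (55–70 ms) and C2 (90–180 ms)
windows.

## Peak extraction

Subject-level band peaks: a straight line is fitted to log10 power against
linear frequency (default 2–120 Hz, excluding the band being fitted) and
subtracted; a bounded Gaussian is fitted inside each conventional band
window (theta 3–8, alpha 8–13, beta 14–30, gamma 30–90 Hz). Theta/alpha/
beta failures fall back to representative cohort peaks (6/10/20 Hz,
flagged); a gamma failure raises. The per-trial estimator fits a single
Gaussian-plus-offset to the raw change spectrum from two starts
(enhancement and suppression) and accepts the location iff the globally
better fit has positive amplitude and a location in (2, 120) Hz. On a
falling 1/f background the ratio bump is skewed a few Hz upward relative to
the gamma component's center; both estimator levels share this skew, so
their agreement (and slope recovery over repetitions) is unaffected.

## Trajectory models

The cohort trajectory is the per-repetition block-average (blocks A–D),
z-scored within subject, averaged over subjects. The breakpoint search
smooths with a centered moving average over 10% of repetitions (truncated
at the edges) and grid-searches a continuous two-segment least-squares fit
(candidates 3–40, ties to the smaller breakpoint; an independent-segments
variant is available). Note a known property: the truncated centered
smoothing distorts the first half-window of the steep early segment and
shifts the fitted breakpoint of a smooth exponential trajectory upward by
roughly two repetitions; on unsmoothed data a hard kink is recovered
exactly. The exponential-plus-linear model y = a·e^(−x/τ) + b·x + c (x =
repetition − 1, a, τ > 0) is fitted by bounded nonlinear least squares with
multi-starts τ ∈ {2, 5, 10, 20}; adjusted R² uses n_params = 4. The decay
form with positive τ is used throughout because the reported time constants
(3.5 and 5.6 repetitions) are decay constants.

## Hierarchical regression

Per-trial responses are modelled as
y = β0 + Subject0 + Orientation0 + β1·repetition + β2·trial +
β3·repeat_block + β4·ITI + β5·microsaccade_rate + β6·pupil_constriction +
β7·early_repetition + ε, with crossed Gaussian random intercepts for
subject and orientation, fitted by REML. The two-variance-component REML
surface is evaluated directly via the Woodbury identity on sufficient
statistics, which makes a full fit cost milliseconds and enables bootstrap
and calibration studies; the implementation reproduces R lmerTest's
estimates, standard errors, Satterthwaite degrees of freedom and p-values
to ~4 significant digits on shared fixtures (a test asserts this). The
early-repetition term defaults to the ramp min(repetition, 10), fitted
jointly with the full repetition regressor; a first-ten indicator variant
exists. The drop over the first ten presentations is read out as
−9·β_early (the early-term contribution; the steady increase is reported
separately as β1 — on noiseless generator truth this readout reproduces the
configured drop exactly). When a covariate serves as the response it is
removed from the right-hand side; pupil analyses also drop the
repeat-block term and exclude blocks A and A2 (pupil size early in a
session is confounded by slow light adaptation).

Inference is dual-gated: a coefficient counts as significant only when its
Satterthwaite p-value is below α = 0.05 (two-tailed) AND its subject-level
case-bootstrap percentile 95% CI (resampled subjects relabeled as distinct,
default 1000 replicates) excludes zero. The gate guards against the
Satterthwaite approximation being anticonservative; under the null its
false-positive rate is at most the nominal level (verified by simulation).
Satterthwaite df are 2·C²/(∇C' V ∇C) with C the coefficient-variance
function of the variance parameters, ∇C a central-difference gradient, and
V twice the inverse numeric Hessian of the −2 REML log-likelihood;
boundary components (variance ratios < 1e−8) are dropped, and the fully
degenerate case returns n − p.

Per-subject slope analyses fit OLS with the same covariates (minus the
random intercepts and the early term, which is collinear within a split)
separately for repetitions 1–10 and 11–120, and correlate the
repetition coefficients across subjects by Spearman rank correlation
(exact permutation null for n ≤ 9, seeded Monte Carlo for 10–12,
asymptotic beyond).

## Nonparametric Granger causality

CSDs are estimated from 0.4–2.0 s post-stimulus in 50%-overlapping 500 ms
windows: each window is detrended by subtracting a Hann-weighted linear
regression fit, Hann-tapered, zero-padded to 1 s (1 Hz grid) and Fourier
transformed; the CSD is the average outer product over windows and trials
(short trials contribute the windows they cover). Wilson's spectral matrix
factorization S(f) = H(f) Σ H(f)^H iterates ψ ← ψ·[ψ⁻¹Sψ⁻ᴴ + I]₊ on the
full FFT circle (causal-part operator with halved, upper-triangularized
zero lag), starting from the Cholesky factor of the lag-0 covariance;
diagonal loading of 1e−8 × mean power is applied only when needed and
logged. On analytic VAR spectra the round-trip residual reaches ~1e−12 and
H and Σ match the generating VAR within 1%. Directed influence uses the
Geweke form GC_{x→y}(f) = ln S_yy / (S_yy − (Σ_xx − Σ_xy²/Σ_yy)|H_yx|²),
clipped at zero; the bivariate decomposition (both directed terms plus the
instantaneous term reconstruct ln S_xx S_yy/det S) is verified to 1e−6.

Repetition contrasts pool trials 11–50 (early; the first ten are excluded
as they carry the steep gamma decrease) versus 81–120 (late). Spectra are
compared by cluster-based sign-flip permutation over frequencies
(cluster-forming threshold α = 0.05 two-sided, mass = summed t, max-mass
null, 1000 permutations default); area-pair changes (gamma-band mean,
cohort peak ± 10 Hz by convention) use a t_max-corrected paired
permutation test with exhaustive sign enumeration for ≤ 12 subjects.
Time-reversal validation reruns the full pipeline on sample-reversed data:
an entry is validated when it is significant forward, its pair is
significant reversed, and the net directed change (x→y minus y→x) flips
sign — a genuinely lagged influence re-appears in the mirrored direction
after reversal, while signal-to-noise asymmetries do not. On the VAR
fixtures this flip holds for weak-to-moderate coupling (lag-1 gains up to
~0.2 at the default oscillator); at very strong coupling the reversed
process itself carries same-direction predictability and the criterion
conservatively withholds validation. The power-confound control regresses
area-pair GC changes on both areas' gamma-power changes and tests the
residual-plus-intercept mean against zero (t-test and pair-level bootstrap
CI). The feedforward/feedback contrast averages validated changes per
subject and direction (hierarchy levels from an editable TSV; feedforward
= source level below target level) and tests the paired difference by
sign-flip permutation; subjects without validated pairs in both directions
are excluded and reported.

## Pupil and gaze processing

Pupil traces are z-scored within subject, baselined to the last 300 ms
before stimulus onset, cleaned by replacing samples deviating more than
1.5 raw MAD (no 1.4826 consistency factor; configurable) from a 250 ms
running median with linear interpolation (per eye, then eyes averaged),
in that order. Constriction is baseline mean minus the 0.5–1.2 s
post-stimulus mean. Note that on white-noise deviations the raw-1.5-MAD
criterion flags ~1/3 of samples by construction (1.5·MAD ≈ 1 σ); on
smooth pupil waveforms with isolated artifacts it behaves as intended, and
idempotence of the replacement holds exactly in that regime.

Microsaccades use the Engbert–Kliegl velocity-threshold method: 5-point
moving-difference velocity, per-dimension thresholds λ·σ with the
median-based σ = √(median(v²) − median(v)²) (λ = 6, minimum duration 6 ms,
monocular), events as runs outside the elliptic criterion. The centered
5-point velocity window gives the detector a ±2-sample onset resolution:
raised-cosine (physiological) events are located with a median error of
one sample; idealized sharp-onset events are flagged exactly two samples
early.

## Problem sizes and numerical choices

Simulation studies in the test suite use cohorts of 8–30 subjects with
full block structure, 50 seeds for trajectory recovery, 100 cohorts for
mixed-model recovery and the dual-gate null (bootstrap 200), and 500 null
simulations for familywise-error calibration — sizes at which the Monte
Carlo error of each check is small relative to its tolerance. Calibration
assertions use the binomial 99% upper bound of the nominal rate at the
simulated sample size, fixed in advance, since a point assertion at the
nominal rate would fail for a perfectly calibrated procedure by sampling
noise alone. All randomness flows from explicit seeds through
`numpy.random.Generator`; permutation and bootstrap p-values use the
add-one convention and are never exactly zero.
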
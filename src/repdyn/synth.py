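"""Synthetic experiments with the statistical structure the analysis assumes.

The generator emulates a blocked grating-repetition session: 30 subjects,
5 blocks (ABCDA2) of 120 trials, per-trial source-level time series with a
1/f background, a repetition-modulated narrowband gamma burst, early evoked
transients and optional line noise; per-trial pupil traces with a light-reflex
constriction; gaze traces with injected microsaccades; coupled source pairs
with directed gamma-band influence; and behavioral reaction times/accuracy.

All ground-truth parameters are exposed so downstream stages can be tested
for parameter recovery. Default effect sizes encode the study conditions:
an early exponential gamma decrease (time constant 3.5 repetitions) riding
on a slow linear increase of 0.40 pp/repetition, a stimulus-unspecific drift
of 0.07 pp/trial, a 7.8 pp persistence offset in the repeat block, a gamma
peak-frequency increase of 0.05 Hz/repetition, and a pupil-constriction
decrease with time constant 5.6 repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialSeries",
    "ExperimentConfig",
    "GammaTrajectoryTruth",
    "PupilTruth",
    "BehaviorTruth",
    "NoiseLevels",
    "CoupledSourceTruth",
    "ExperimentDataset",
    "block_labels",
    "generate_trial_table",
    "generate_experiment",
    "generate_coupled_pair",
    "generate_pupil_trace",
    "generate_gaze_trace",
    "var_spectral_matrix",
    "parametric_gc",
]

ORIENTATIONS = (22.5, 67.5, 112.5, 157.5)


@dataclass
class TrialSeries:
    """One epoch of one source/channel (or a channel stack).

    data has shape (n_samples,) or (n_channels, n_samples); times is the
    event-aligned axis in seconds (0 = stimulus onset).
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[-1] != self.times.shape[0]:
            raise ValueError("data and times length mismatch")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]


def block_labels(n_blocks: int = 5) -> list[str]:
    """Block sequence; the last block repeats the first block's orientation."""
    base = ["A", "B", "C", "D"]
    if n_blocks < 2 or n_blocks > 5:
        raise ValueError("n_blocks must be in 2..5")
    return base[: n_blocks - 1] + ["A2"]


@dataclass
class ExperimentConfig:
    n_subjects: int = 30
    n_blocks: int = 5
    trials_per_block: int = 120
    fs: float = 1200.0
    baseline_dur: float = 1.0
    stim_dur_x0: float = 1.65
    stim_dur_fwhm: float = 0.2
    stim_dur_range: tuple[float, float] = (0.3, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_block < 12:
            raise ValueError("trials_per_block must be >= 12")
        if self.fs <= 2 * 120:
            raise ValueError("fs must exceed twice the highest simulated frequency")

    @property
    def blocks(self) -> list[str]:
        return block_labels(self.n_blocks)


@dataclass
class GammaTrajectoryTruth:
    """Ground-truth repetition trajectory of induced gamma power and frequency.

    Per-repetition amplitude (power change, percentage points):
        y(r, t, block) = a * exp(-(r-1)/tau) + b*(r-1) + c
                         + trial_slope*(t-1) + a2_boost * 1[block == A2]
    with r the 1-based repetition number and t the 1-based total trial number.
    ``a`` defaults to 39.2 pp so the linear early-readout (joint ramp + linear
    regression over repetitions 1-120) equals a 30.8 pp drop over the first
    ten presentations.
    """

    a: float = 39.2
    tau: float = 3.5
    b: float = 0.40
    c: float = 60.0
    f0: float = 52.0
    f_slope: float = 0.05
    trial_slope: float = 0.07
    a2_boost: float = 7.8
    f_trial_slope: float = -0.01
    f_a2_boost: float = 3.2

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not (30.0 < self.f0 < 90.0):
            raise ValueError("f0 must lie in (30, 90) Hz")

    def power(self, repetition, trial, is_a2) -> np.ndarray:
        r = np.asarray(repetition, dtype=float)
        t = np.asarray(trial, dtype=float)
        a2 = np.asarray(is_a2, dtype=float)
        return (self.a * np.exp(-(r - 1) / self.tau) + self.b * (r - 1) + self.c
                + self.trial_slope * (t - 1) + self.a2_boost * a2)

    def freq(self, repetition, trial, is_a2) -> np.ndarray:
        r = np.asarray(repetition, dtype=float)
        t = np.asarray(trial, dtype=float)
        a2 = np.asarray(is_a2, dtype=float)
        return (self.f0 + self.f_slope * (r - 1) + self.f_trial_slope * (t - 1)
                + self.f_a2_boost * a2)

    def validate(self, n_repetitions: int, n_trials: int) -> None:
        r = np.arange(1, n_repetitions + 1, dtype=float)
        t = np.linspace(1, n_trials, n_repetitions)
        for a2 in (0.0, 1.0):
            if np.any(self.power(r, t, a2) < 0):
                raise ValueError(
                    "trajectory produces negative gamma amplitude; "
                    "adjust a, b, c or trial_slope")


@dataclass
class PupilTruth:
    """Repetition decay of the light-reflex constriction depth (z-units)."""

    depth0: float = 1.4
    depth_inf: float = 0.8
    tau: float = 5.6

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def depth(self, repetition) -> np.ndarray:
        r = np.asarray(repetition, dtype=float)
        return self.depth_inf + (self.depth0 - self.depth_inf) * np.exp(-(r - 1) / self.tau)


@dataclass
class BehaviorTruth:
    """Reaction-time and accuracy trajectory (shifted-lognormal RT)."""

    rt_base_ms: float = 496.0
    rt_early_drop_ms: float = 15.0     # speed-up over the first 10 repetitions
    rt_rep_slope_ms: float = 0.1
    rt_trial_slope_ms: float = -0.07
    rt_a2_ms: float = 12.0
    rt_shift_ms: float = 200.0
    rt_sigma: float = 0.35
    accuracy: float = 0.69

    def rt_det(self, repetition, trial, is_a2) -> np.ndarray:
        """Deterministic RT trend: elevated on the first presentations of a
        block (decaying to baseline by repetition 10), plus slow linear
        trends and the repeat-block offset."""
        r = np.asarray(repetition, dtype=float)
        t = np.asarray(trial, dtype=float)
        a2 = np.asarray(is_a2, dtype=float)
        return (self.rt_base_ms
                + self.rt_early_drop_ms * (10 - np.minimum(r, 10)) / 9.0
                + self.rt_rep_slope_ms * (r - 1)
                + self.rt_trial_slope_ms * (t - 1)
                + self.rt_a2_ms * a2)


@dataclass
class NoiseLevels:
    """Per-trial measurement noise and between-subject heterogeneity."""

    gamma_sd: float = 110.0          # pp; single-trial power estimates are noisy
    freq_sd: float = 8.0             # Hz
    pupil_sd: float = 1.25           # z-units
    erf_sd: float = 2.0
    subject_intercept_sd: float = 30.0   # pp, gamma power
    orientation_intercept_sd: float = 5.0
    subject_amp_frac_sd: float = 0.30    # fractional spread of early-decay amplitude
    gamma_pupil_amp_corr: float = 0.45   # across-subject coupling of early decays
    ms_rate_mean: float = 1.5
    ms_rate_trial_slope: float = -0.0004
    ms_rate_sd: float = 0.6


@dataclass
class ErfTruth:
    """Evoked-component magnitudes: linear repetition decreases."""

    c1_base: float = 10.0
    c1_rep_slope: float = -0.01
    c1_early_drop: float = 1.0
    c1_a2: float = -0.3
    c2_base: float = 20.0
    c2_rep_slope: float = -0.02
    c2_early_drop: float = 0.8
    c2_trial_slope: float = -0.005
    c2_a2: float = -0.4


def _trial_skeleton(config: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial metadata: subject, block, orientation, repetition, trial,
    stimulus duration and inter-trial interval."""
    rows = []
    blocks = config.blocks
    for s in range(1, config.n_subjects + 1):
        orients = rng.permutation(ORIENTATIONS)
        omap = {b: orients[i % 4] for i, b in enumerate(["A", "B", "C", "D"])}
        omap["A2"] = omap["A"]
        trial = 0
        for b in blocks:
            for r in range(1, config.trials_per_block + 1):
                trial += 1
                rows.append((s, b, omap[b], r, trial))
    df = pd.DataFrame(rows, columns=["subject", "block", "orientation",
                                     "repetition", "trial"])
    n = len(df)
    # truncated Cauchy stimulus durations
    lo, hi = config.stim_dur_range
    gamma_hw = config.stim_dur_fwhm / 2.0
    u_lo = math.atan((lo - config.stim_dur_x0) / gamma_hw)
    u_hi = math.atan((hi - config.stim_dur_x0) / gamma_hw)
    u = rng.uniform(u_lo, u_hi, size=n)
    df["stim_dur_s"] = config.stim_dur_x0 + gamma_hw * np.tan(u)
    df["iti_s"] = np.clip(rng.lognormal(mean=0.3, sigma=0.4, size=n), 0.5, 4.0)
    df["is_a2"] = (df["block"] == "A2").astype(int)
    return df


def generate_trial_table(config: ExperimentConfig | None = None,
                         truth: GammaTrajectoryTruth | None = None,
                         pupil: PupilTruth | None = None,
                         behavior: BehaviorTruth | None = None,
                         erf: ErfTruth | None = None,
                         noise: NoiseLevels | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the per-trial measure table the regression stages consume.

    Columns: subject, block, orientation, repetition, trial, stim_dur_s,
    iti_s, rt_ms, correct, ms_rate, pupil_constriction, gamma_power,
    gamma_freq, erf_c1, erf_c2 (measures carry additive noise per
    ``noise``; ground truth is recoverable from the truth objects).
    """
    config = config or ExperimentConfig()
    truth = truth or GammaTrajectoryTruth()
    pupil = pupil or PupilTruth()
    behavior = behavior or BehaviorTruth()
    erf = erf or ErfTruth()
    noise = noise or NoiseLevels()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth.validate(config.trials_per_block, config.n_blocks * config.trials_per_block)

    df = _trial_skeleton(config, rng)
    n = len(df)
    r = df["repetition"].to_numpy(float)
    t = df["trial"].to_numpy(float)
    a2 = df["is_a2"].to_numpy(float)
    subj = df["subject"].to_numpy()

    # correlated between-subject spread of the early-decay amplitudes
    rho = noise.gamma_pupil_amp_corr
    cov = np.array([[1.0, rho], [rho, 1.0]]) * noise.subject_amp_frac_sd ** 2
    amp_dev = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_subjects)
    amp_dev = np.clip(amp_dev, -0.9, None)
    g_fac = 1.0 + amp_dev[subj - 1, 0]
    p_fac = 1.0 + amp_dev[subj - 1, 1]

    subj_int = rng.normal(0.0, noise.subject_intercept_sd, config.n_subjects)
    ori_levels = {o: i for i, o in enumerate(ORIENTATIONS)}
    ori_int = rng.normal(0.0, noise.orientation_intercept_sd, len(ORIENTATIONS))
    ori_idx = df["orientation"].map(ori_levels).to_numpy()

    exp_term = np.exp(-(r - 1) / truth.tau)
    g_true = (truth.a * g_fac * exp_term + truth.b * (r - 1) + truth.c
              + truth.trial_slope * (t - 1) + truth.a2_boost * a2)
    df["gamma_power"] = (g_true + subj_int[subj - 1] + ori_int[ori_idx]
                         + rng.normal(0.0, noise.gamma_sd, n))
    df["gamma_freq"] = truth.freq(r, t, a2) + rng.normal(0.0, noise.freq_sd, n)

    depth = (pupil.depth_inf
             + (pupil.depth0 - pupil.depth_inf) * p_fac * np.exp(-(r - 1) / pupil.tau))
    df["pupil_constriction"] = depth + rng.normal(0.0, noise.pupil_sd, n)

    # shifted-lognormal noise with mean equal to rt_base - shift, so the
    # trial mean follows the deterministic trend
    rt_det = behavior.rt_det(r, t, a2)
    ln_mu = math.log(max(behavior.rt_base_ms - behavior.rt_shift_ms, 1.0)) \
        - behavior.rt_sigma ** 2 / 2.0
    rt_noise = rng.lognormal(ln_mu, behavior.rt_sigma, n)
    df["rt_ms"] = rt_det + rt_noise - (behavior.rt_base_ms - behavior.rt_shift_ms)
    df["correct"] = (rng.uniform(size=n) < behavior.accuracy).astype(int)

    df["ms_rate"] = np.clip(
        noise.ms_rate_mean + noise.ms_rate_trial_slope * (t - 1)
        + rng.normal(0.0, noise.ms_rate_sd, n), 0.0, None)

    df["erf_c1"] = (erf.c1_base + erf.c1_early_drop * (np.minimum(r, 10) - 10) / 9.0
                    + erf.c1_rep_slope * (r - 1) + erf.c1_a2 * a2
                    + rng.normal(0.0, noise.erf_sd, n))
    df["erf_c2"] = (erf.c2_base + erf.c2_early_drop * (np.minimum(r, 10) - 10) / 9.0
                    + erf.c2_rep_slope * (r - 1) + erf.c2_trial_slope * (t - 1)
                    + erf.c2_a2 * a2 + rng.normal(0.0, noise.erf_sd, n))
    return df


# ---------------------------------------------------------------------------
# time-series generation
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, fs: float, chi: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^chi,
    normalized to unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-chi / 2.0)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(n: int, fs: float, fc: float, fwhm: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian-spectral-profile narrowband noise centered at fc, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    shape = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class ExperimentDataset:
    """Container returned by generate_experiment: trial time series plus the
    per-trial metadata table and the generating truth."""

    trials: list
    metadata: pd.DataFrame
    truth: GammaTrajectoryTruth
    config: ExperimentConfig

    def __len__(self) -> int:
        return len(self.trials)

    def to_dir(self, path) -> None:
        """Write metadata as TSV and time series as an .npz array container."""
        import pathlib
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(path / "trials.tsv", sep="\t", index=False)
        arrays = {f"trial_{i:05d}": ts.data for i, ts in enumerate(self.trials)}
        arrays.update({f"times_{i:05d}": ts.times for i, ts in enumerate(self.trials)})
        np.savez(path / "series.npz", fs=self.config.fs, **arrays)

    @staticmethod
    def read_metadata(path) -> pd.DataFrame:
        import pathlib
        return pd.read_csv(pathlib.Path(path) / "trials.tsv", sep="\t")


def generate_experiment(config: ExperimentConfig | None = None,
                        truth: GammaTrajectoryTruth | None = None,
                        chi: float = 2.0,
                        gamma_fwhm: float = 10.0,
                        gamma_scale: float = 0.02,
                        bg_scale: float = 1.0,
                        erf_scale: float = 0.05,
                        erf: ErfTruth | None = None,
                        line_amp: float = 0.0,
                        line_freq: float = 50.0,
                        envelope_ramp: float = 0.1,
                        rng: np.random.Generator | None = None) -> ExperimentDataset:
    """Generate per-trial source-level time series for one virtual V1/V2
    source per subject.

    Each trial is baseline (-baseline_dur..0) plus stimulation (0..stim_dur):
    1/f^chi background + amplitude-modulated narrowband gamma present only
    post-stimulus (center frequency and power follow ``truth``) + evoked
    transients at 60 and 120 ms whose amplitudes decay with repetition +
    optional line component. Deterministic for a fixed config.seed.
    """
    config = config or ExperimentConfig()
    truth = truth or GammaTrajectoryTruth()
    erf = erf or ErfTruth()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth.validate(config.trials_per_block, config.n_blocks * config.trials_per_block)
    meta = _trial_skeleton(config, rng)
    fs = config.fs
    n_pre = int(round(config.baseline_dur * fs))
    trials = []
    g_power, g_freq = [], []
    for row in meta.itertuples(index=False):
        n_post = int(round(row.stim_dur_s * fs))
        n = n_pre + n_post
        times = (np.arange(n) - n_pre) / fs
        x = np.zeros(n)
        if bg_scale > 0:
            x += bg_scale * _one_over_f_noise(n, fs, chi, rng)
        fc = float(truth.freq(row.repetition, row.trial, row.is_a2))
        target = float(truth.power(row.repetition, row.trial, row.is_a2))
        g = _narrowband_noise(n, fs, fc, gamma_fwhm, rng)
        env = np.clip(times / max(envelope_ramp, 1.0 / fs), 0.0, 1.0)
        env[times < 0] = 0.0
        g = g * env
        # normalize mean power over the steady stimulation window to the
        # configured trajectory value (in gamma_scale units)
        sel = times >= envelope_ramp
        p = np.mean(g[sel] ** 2) if sel.any() else 0.0
        if p > 0:
            g *= math.sqrt(gamma_scale * target / p)
        x += g
        if erf_scale > 0:
            c1 = (erf.c1_base + erf.c1_early_drop * (min(row.repetition, 10) - 10) / 9.0
                  + erf.c1_rep_slope * (row.repetition - 1) + erf.c1_a2 * row.is_a2)
            c2 = (erf.c2_base + erf.c2_early_drop * (min(row.repetition, 10) - 10) / 9.0
                  + erf.c2_rep_slope * (row.repetition - 1)
                  + erf.c2_trial_slope * (row.trial - 1) + erf.c2_a2 * row.is_a2)
            x += erf_scale * c1 * np.exp(-0.5 * ((times - 0.060) / 0.008) ** 2)
            x -= erf_scale * c2 * np.exp(-0.5 * ((times - 0.120) / 0.030) ** 2)
        if line_amp > 0:
            x += line_amp * np.sin(2 * np.pi * line_freq * times
                                   + rng.uniform(0, 2 * np.pi))
        trials.append(TrialSeries(x, fs, times,
                                  meta=dict(subject=row.subject, block=row.block,
                                            orientation=row.orientation,
                                            repetition=row.repetition,
                                            trial=row.trial)))
        g_power.append(target)
        g_freq.append(fc)
    meta = meta.copy()
    meta["gamma_power_true"] = g_power
    meta["gamma_freq_true"] = g_freq
    return ExperimentDataset(trials=trials, metadata=meta, truth=truth, config=config)


# ---------------------------------------------------------------------------
# coupled source pairs and the parametric GC oracle
# ---------------------------------------------------------------------------

@dataclass
class CoupledSourceTruth:
    """Bivariate VAR ground truth for directed gamma-band influence.

    ``var_coefficients`` has shape (lags, 2, 2); channel 1 (index 0) Granger-
    causes channel 2 (index 1) when var_coefficients[k][1, 0] != 0.
    """

    var_coefficients: np.ndarray
    noise_cov: np.ndarray

    def __post_init__(self):
        self.var_coefficients = np.asarray(self.var_coefficients, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.var_coefficients.ndim != 3 or self.var_coefficients.shape[1:] != (2, 2):
            raise ValueError("var_coefficients must have shape (lags, 2, 2)")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        rad = self.spectral_radius()
        if rad >= 1.0:
            raise ValueError(f"VAR process unstable (companion spectral radius {rad:.3f})")

    def spectral_radius(self) -> float:
        p = self.var_coefficients.shape[0]
        k = self.var_coefficients.shape[1]
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = np.concatenate(self.var_coefficients, axis=1)
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    @classmethod
    def gamma_oscillator(cls, fs: float = 1200.0, f_osc: float = 60.0,
                         rho: float = 0.9, coupling: float = 0.3,
                         noise_cov: np.ndarray | None = None) -> "CoupledSourceTruth":
        """VAR(2) pair of damped gamma oscillators; channel 1 drives channel 2
        with lag-1 gain ``coupling``."""
        a1 = 2 * rho * math.cos(2 * math.pi * f_osc / fs)
        a2 = -rho ** 2
        A = np.zeros((2, 2, 2))
        A[0] = np.array([[a1, 0.0], [coupling, a1]])
        A[1] = np.array([[a2, 0.0], [0.0, a2]])
        if noise_cov is None:
            noise_cov = np.eye(2)
        return cls(A, noise_cov)


def generate_coupled_pair(truth: CoupledSourceTruth, n_trials: int,
                          trial_dur: float = 2.0, fs: float = 1200.0,
                          burn_in: float = 0.5,
                          rng: np.random.Generator | None = None,
                          seed: int = 0) -> list[TrialSeries]:
    """Simulate two-channel trials from the VAR ground truth.

    Returns TrialSeries with data shape (2, n_samples); channel order matches
    the VAR ordering, so channel 0 Granger-causes channel 1 for a lower-
    triangular coefficient stack.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    A = truth.var_coefficients
    p = A.shape[0]
    L = np.linalg.cholesky(truth.noise_cov)
    n = int(round(trial_dur * fs))
    nb = int(round(burn_in * fs))
    times = np.arange(n) / fs
    trials = []
    for _ in range(n_trials):
        e = rng.normal(size=(n + nb + p, 2)) @ L.T
        x = np.zeros((n + nb + p, 2))
        for t in range(p, n + nb + p):
            acc = e[t].copy()
            for k in range(p):
                acc += A[k] @ x[t - 1 - k]
            x[t] = acc
        trials.append(TrialSeries(x[nb + p:].T, fs, times))
    return trials


def var_spectral_matrix(A: np.ndarray, sigma: np.ndarray, freqs: np.ndarray,
                        fs: float):
    """Analytic transfer function and spectral matrix of a stable VAR.

    Returns (H, S) with shapes (n_freqs, k, k); S(f) = H(f) Sigma H(f)^H / fs
    up to a constant density normalization (the constant cancels in GC).
    """
    A = np.asarray(A, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    k = A.shape[1]
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, A.shape[0] + 1)) / fs)
    Af = np.tile(np.eye(k, dtype=complex), (len(freqs), 1, 1))
    for kk in range(A.shape[0]):
        Af -= z[:, kk, None, None] * A[kk]
    H = np.linalg.inv(Af)
    S = H @ sigma @ np.conj(np.swapaxes(H, 1, 2))
    return H, S


def _gc_from_transfer(H: np.ndarray, sigma: np.ndarray, i: int, j: int) -> np.ndarray:
    """Geweke spectral GC from channel i to channel j given H(f) and Sigma."""
    S = H @ sigma @ np.conj(np.swapaxes(H, 1, 2))
    syy = S[:, j, j].real
    sig_cond = sigma[i, i] - sigma[i, j] ** 2 / sigma[j, j]
    denom = syy - sig_cond * np.abs(H[:, j, i]) ** 2
    denom = np.maximum(denom, np.finfo(float).tiny)
    return np.log(np.maximum(syy, np.finfo(float).tiny) / denom)


def parametric_gc(truth: CoupledSourceTruth, freqs: np.ndarray, fs: float):
    """Closed-form spectral GC of the generating VAR (oracle for the
    nonparametric pipeline). Returns (gc_1to2, gc_2to1) arrays."""
    H, _ = var_spectral_matrix(truth.var_coefficients, truth.noise_cov, freqs, fs)
    return (_gc_from_transfer(H, truth.noise_cov, 0, 1),
            _gc_from_transfer(H, truth.noise_cov, 1, 0))


# ---------------------------------------------------------------------------
# pupil and gaze fixtures
# ---------------------------------------------------------------------------

def generate_pupil_trace(repetition: int, truth: PupilTruth | None = None,
                         fs: float = 1000.0, baseline_dur: float = 1.0,
                         post_dur: float = 1.5, baseline_level: float = 5.0,
                         noise_sd: float = 0.05, n_spikes: int = 0,
                         spike_amp: float = 3.0, n_dropouts: int = 0,
                         dropout_dur: float = 0.03,
                         rng: np.random.Generator | None = None, seed: int = 0):
    """One trial's pupil-size trace with a light-reflex constriction.

    Constriction depth decays exponentially over repetitions (truth.tau);
    the waveform ramps from 0.3 s to 0.5 s post-stimulus and stays at the
    constricted plateau, so the 0.5-1.2 s metric equals the configured depth
    exactly at noise 0. Optional spike artifacts and blink-like dropouts are
    injected for outlier-replacement testing. Returns (times, samples).
    """
    truth = truth or PupilTruth()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_pre = int(round(baseline_dur * fs))
    n_post = int(round(post_dur * fs))
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    depth = float(truth.depth(repetition))
    shape = np.clip((times - 0.3) / 0.2, 0.0, 1.0)
    shape[times < 0.3] = 0.0
    x = baseline_level - depth * shape
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    for _ in range(n_spikes):
        i = rng.integers(n_pre // 2, x.size - 2)
        x[i] += spike_amp * rng.choice([-1.0, 1.0])
    for _ in range(n_dropouts):
        i = rng.integers(0, x.size - int(dropout_dur * fs) - 1)
        x[i:i + int(dropout_dur * fs)] -= spike_amp
    return times, x


def generate_gaze_trace(duration: float = 2.0, fs: float = 1000.0,
                        ms_rate: float = 1.5,
                        amp_range: tuple[float, float] = (0.1, 1.0),
                        dur_range: tuple[float, float] = (0.006, 0.025),
                        drift_sd: float = 0.05, noise_sd: float = 0.0,
                        min_separation: float = 0.1,
                        profile: str = "cosine",
                        rng: np.random.Generator | None = None, seed: int = 0):
    """Fixational gaze trace (degrees) with Poisson-injected microsaccades.

    Microsaccades follow a raised-cosine velocity profile by default (peak
    velocity pi*amplitude/(2*duration), i.e. main-sequence scaling with
    amplitude); ``profile='constant'`` injects constant-velocity events with
    a sharp onset. Returns (times, xy array (n, 2), events) where events is
    a list of dicts with onset/offset/amplitude/peak_velocity ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    # fixational drift: low-passed random walk; the 20 ms kernel keeps it
    # rough enough for the median-based velocity-spread estimator
    steps = rng.normal(0.0, 1.0, size=(n, 2))
    from scipy.ndimage import gaussian_filter1d
    drift = np.cumsum(steps, axis=0)
    drift = gaussian_filter1d(drift, sigma=0.02 * fs, axis=0)
    sd = drift.std(axis=0)
    sd[sd == 0] = 1.0
    xy = drift / sd * drift_sd
    events = []
    n_events = rng.poisson(ms_rate * duration)
    onsets = []
    attempts = 0
    while len(onsets) < n_events and attempts < 1000:
        attempts += 1
        t0 = rng.uniform(0.05, duration - dur_range[1] - 0.05)
        if all(abs(t0 - o) > min_separation for o in onsets):
            onsets.append(t0)
    for t0 in sorted(onsets):
        amp = rng.uniform(*amp_range)
        dur = rng.uniform(*dur_range)
        theta = rng.uniform(0, 2 * np.pi)
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + dur) * fs)), n - 1)
        if i1 <= i0:
            continue
        tt = (np.arange(i1 - i0) + 0.5) / (i1 - i0)
        if profile == "constant":
            disp = amp * tt
            pv = amp / dur
        else:
            disp = amp * 0.5 * (1 - np.cos(np.pi * tt))  # 0 -> amp
            pv = np.pi * amp / (2 * dur)
        step = np.zeros(n)
        step[i0:i1] = disp
        step[i1:] = amp
        xy[:, 0] += step * math.cos(theta)
        xy[:, 1] += step * math.sin(theta)
        events.append(dict(onset=i0 / fs, offset=i1 / fs, amplitude=amp,
                           peak_velocity=pv))
    if noise_sd > 0:
        xy = xy + rng.normal(0.0, noise_sd, xy.shape)
    return times, xy, events
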
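"""Per-trial spectra, power change versus baseline, time-frequency maps and
evoked-field component magnitudes.

The windowing scheme is dual-band: frequencies up to 20 Hz come from Hann-
tapered 0.5 s windows (2 Hz resolution), frequencies above 20 Hz from 1/3 s
windows with three Slepian tapers. Windows overlap by 50%, are demeaned and
linearly detrended, and zero-padded to 1 s, which puts both bands on a common
1 Hz grid. Power is normalized so that the one-sided spectrum sums to the
taper-weighted signal variance (Parseval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import detrend as _sp_detrend
from scipy.signal.windows import dpss, hann

from .synth import TrialSeries

__all__ = [
    "TaperScheme",
    "PowerSpectrum",
    "PowerChangeSpectrum",
    "TFMap",
    "ERFComponents",
    "dft_line_filter",
    "trial_power",
    "power_change",
    "baseline_block_means",
    "time_frequency",
    "erf",
]


@dataclass(frozen=True)
class TaperScheme:
    """Dual-band windowing/tapering scheme.

    Frequencies <= ``band_edge`` use ``low_window`` s Hann windows; higher
    frequencies use ``high_window`` s windows with ``n_tapers`` Slepian
    tapers (time-half-bandwidth ``nw``; three well-concentrated tapers on a
    1/3 s window imply nw = 2, i.e. +/-6 Hz concentration). All windows
    overlap by ``overlap`` and are zero-padded to ``zero_pad_to`` s.
    """

    band_edge: float = 20.0
    low_window: float = 0.5
    high_window: float = 1.0 / 3.0
    n_tapers: int = 3
    nw: float = 2.0
    overlap: float = 0.5
    zero_pad_to: float = 1.0
    fmax: float = 120.0

    def __post_init__(self):
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if self.zero_pad_to < max(self.low_window, self.high_window):
            raise ValueError("zero_pad_to must be >= window length")


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    n_windows: int = 0
    trial: int | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)


@dataclass
class PowerChangeSpectrum:
    """Per-trial stimulus/baseline power ratio on the dual-band grid."""

    freqs: np.ndarray
    change: np.ndarray
    trial: int | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.change = np.asarray(self.change, dtype=float)

    @property
    def percent_points(self) -> np.ndarray:
        """(ratio - 1) * 100, the induced power change in percentage points."""
        return (self.change - 1.0) * 100.0


@dataclass
class TFMap:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), NaN where no full window fits


@dataclass
class ERFComponents:
    """Per-trial evoked component magnitudes: C1 (55-70 ms) and C2 (90-180 ms)."""

    c1_magnitude: np.ndarray
    c2_magnitude: np.ndarray
    trial: np.ndarray | None = None

    C1_WINDOW = (0.055, 0.070)
    C2_WINDOW = (0.090, 0.180)


def dft_line_filter(ts: TrialSeries, line_freqs) -> TrialSeries:
    """Remove line components by subtracting the least-squares sinusoid fit
    at each listed frequency over the whole epoch. Other frequencies are
    unchanged up to numerical precision; an empty list is the identity."""
    line_freqs = list(line_freqs)
    if not line_freqs:
        return TrialSeries(ts.data.copy(), ts.fs, ts.times.copy(), dict(ts.meta))
    for f in line_freqs:
        if f >= ts.fs / 2:
            raise ValueError(f"line frequency {f} Hz above Nyquist ({ts.fs / 2} Hz)")
    t = ts.times
    cols = []
    for f in line_freqs:
        cols.append(np.cos(2 * np.pi * f * t))
        cols.append(np.sin(2 * np.pi * f * t))
    X = np.column_stack(cols)
    data = np.atleast_2d(ts.data)
    coef, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    clean = data - (X @ coef).T
    if ts.data.ndim == 1:
        clean = clean[0]
    return TrialSeries(clean, ts.fs, ts.times.copy(), dict(ts.meta))


def _window_starts(n_epoch: int, n_win: int, overlap: float) -> np.ndarray:
    step = max(1, int(round(n_win * (1.0 - overlap))))
    starts = np.arange(0, n_epoch - n_win + 1, step)
    if starts.size == 0:
        raise ValueError("epoch shorter than analysis window")
    return starts


def _band_power(x: np.ndarray, fs: float, win_s: float, tapers: np.ndarray,
                overlap: float, zero_pad_to: float):
    """Average tapered periodogram over 50%-overlapping windows.

    ``tapers`` has shape (n_tapers, n_win) with unit-energy rows. Power is
    one-sided and sums (over the full grid) to the mean taper-weighted
    variance of the detrended windows."""
    n_win = tapers.shape[1]
    n_pad = int(round(zero_pad_to * fs))
    starts = _window_starts(x.size, n_win, overlap)
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    for s in starts:
        seg = x[s:s + n_win]
        seg = _sp_detrend(seg, type="linear")
        for w in tapers:
            X = np.fft.rfft(w * seg, n=n_pad)
            p = np.abs(X) ** 2 / n_pad
            p[1:] *= 2.0
            if n_pad % 2 == 0:
                p[-1] /= 2.0
            acc += p
    acc /= starts.size * tapers.shape[0]
    return freqs, acc, starts.size


def _unit_energy(w: np.ndarray) -> np.ndarray:
    return w / math.sqrt(np.sum(w ** 2))


def _scheme_tapers(scheme: TaperScheme, fs: float):
    n_low = int(round(scheme.low_window * fs))
    n_high = int(round(scheme.high_window * fs))
    low = _unit_energy(hann(n_low, sym=False))[None, :]
    high = dpss(n_high, scheme.nw, Kmax=scheme.n_tapers)
    high = np.array([_unit_energy(w) for w in high])
    return low, high


def trial_power(ts: TrialSeries, epoch: tuple[float, float],
                scheme: TaperScheme | None = None) -> PowerSpectrum:
    """Dual-band power spectrum of one epoch of one trial.

    The low band (f <= band_edge) uses the Hann path, the high band the
    Slepian multitaper path; both are concatenated on the common 1 Hz grid
    (spacing 1/zero_pad_to).
    """
    scheme = scheme or TaperScheme()
    t0, t1 = epoch
    if t0 < ts.times[0] - 1e-9 or t1 > ts.times[-1] + 1.0 / ts.fs + 1e-9:
        raise ValueError("epoch outside trial")
    sel = (ts.times >= t0 - 1e-9) & (ts.times < t1 - 1e-9)
    x = np.asarray(ts.data, dtype=float)
    if x.ndim != 1:
        raise ValueError("trial_power expects a single channel")
    x = x[sel]
    low_t, high_t = _scheme_tapers(scheme, ts.fs)
    f_lo, p_lo, nw_lo = _band_power(x, ts.fs, scheme.low_window, low_t,
                                    scheme.overlap, scheme.zero_pad_to)
    f_hi, p_hi, nw_hi = _band_power(x, ts.fs, scheme.high_window, high_t,
                                    scheme.overlap, scheme.zero_pad_to)
    lo_sel = (f_lo > 0) & (f_lo <= scheme.band_edge)
    hi_sel = (f_hi > scheme.band_edge) & (f_hi <= scheme.fmax)
    freqs = np.concatenate([f_lo[lo_sel], f_hi[hi_sel]])
    power = np.concatenate([p_lo[lo_sel], p_hi[hi_sel]])
    return PowerSpectrum(freqs, power, n_windows=nw_lo + nw_hi,
                         trial=ts.meta.get("trial"))


def baseline_block_means(spectra: list[PowerSpectrum], blocks) -> dict:
    """Mean baseline spectrum per block over all (artifact-free) trials."""
    blocks = np.asarray(blocks)
    out = {}
    for b in np.unique(blocks):
        sel = [sp for sp, bb in zip(spectra, blocks) if bb == b]
        out[b] = PowerSpectrum(sel[0].freqs,
                               np.mean([sp.power for sp in sel], axis=0))
    return out


def power_change(stim: PowerSpectrum, baseline: PowerSpectrum) -> PowerChangeSpectrum:
    """Elementwise stimulus/baseline power ratio (baseline: block-mean
    spectrum of the same subject and block)."""
    if stim.freqs.shape != baseline.freqs.shape or \
            not np.allclose(stim.freqs, baseline.freqs):
        raise ValueError("frequency grids differ")
    if np.any(baseline.power <= 0):
        raise ValueError("baseline power must be positive")
    return PowerChangeSpectrum(stim.freqs.copy(), stim.power / baseline.power,
                               trial=stim.trial)


def time_frequency(ts: TrialSeries, scheme: TaperScheme | None = None,
                   zero_pad_to: float = 4.0, tmin: float = -1.0,
                   tmax: float = 1.3, step_s: float | None = None) -> TFMap:
    """Time-frequency map: the trial_power scheme with windows centered on
    each time point and zero-padding to 4 s (0.25 Hz grid).

    ``step_s`` decimates the time axis (default: one estimate per sample).
    Time points whose window extends beyond the epoch are NaN, not zero.
    """
    scheme = scheme or TaperScheme()
    scheme = TaperScheme(band_edge=scheme.band_edge, low_window=scheme.low_window,
                         high_window=scheme.high_window, n_tapers=scheme.n_tapers,
                         nw=scheme.nw, overlap=scheme.overlap,
                         zero_pad_to=zero_pad_to, fmax=scheme.fmax)
    fs = ts.fs
    step = 1 if step_s is None else max(1, int(round(step_s * fs)))
    centers = np.arange(int(round(tmin * fs)), int(round(tmax * fs)) + 1, step)
    x = np.asarray(ts.data, dtype=float)
    n = x.size
    i_t0 = int(round(ts.times[0] * fs))
    low_t, high_t = _scheme_tapers(scheme, fs)
    n_pad = int(round(zero_pad_to * fs))
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    lo_sel = (freqs > 0) & (freqs <= scheme.band_edge)
    hi_sel = (freqs > scheme.band_edge) & (freqs <= scheme.fmax)
    out_f = np.concatenate([freqs[lo_sel], freqs[hi_sel]])
    out = np.full((out_f.size, centers.size), np.nan)
    for j, c in enumerate(centers):
        cols = []
        for tapers, fsel in ((low_t, lo_sel), (high_t, hi_sel)):
            n_win = tapers.shape[1]
            a = c - i_t0 - n_win // 2
            b = a + n_win
            if a < 0 or b > n:
                cols.append(np.full(fsel.sum(), np.nan))
                continue
            seg = _sp_detrend(x[a:b], type="linear")
            p = np.zeros(freqs.size)
            for w in tapers:
                X = np.fft.rfft(w * seg, n=n_pad)
                pk = np.abs(X) ** 2 / n_pad
                pk[1:] *= 2.0
                p += pk
            p /= tapers.shape[0]
            cols.append(p[fsel])
        out[:, j] = np.concatenate(cols)
    return TFMap(times=centers / fs, freqs=out_f, power=out)


def gaussian_lowpass(x: np.ndarray, fs: float, f_6db: float = 80.0) -> np.ndarray:
    """Acausal Gaussian low-pass with -6 dB (amplitude 0.5) at ``f_6db``."""
    sigma_t = math.sqrt(math.log(2.0) / 2.0) / (math.pi * f_6db)
    return gaussian_filter1d(x, sigma=sigma_t * fs, axis=-1, mode="nearest")


def erf(trials: list[TrialSeries], window: tuple[float, float] = (-0.2, 0.6),
        baseline: tuple[float, float] = (-0.2, 0.0), f_6db: float = 80.0):
    """Event-related field and per-trial component magnitudes.

    Each trial is low-pass filtered (acausal Gaussian kernel, -6 dB at
    80 Hz), baseline-subtracted and cropped to ``window``; the ERF is the
    trial average. Component magnitude is the mean absolute filtered
    deflection in the C1 (55-70 ms) / C2 (90-180 ms) windows, per trial.
    Returns (times, erf_average, ERFComponents).
    """
    if not trials:
        raise ValueError("need at least one trial")
    fs = trials[0].fs
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    times = np.arange(i0, i1) / fs
    filtered = []
    c1, c2, ids = [], [], []
    for ts in trials:
        if ts.times[0] > window[0] + 1e-9 or ts.times[-1] < window[1] - 1e-9:
            raise ValueError("trial does not cover the ERF window")
        y = gaussian_lowpass(np.asarray(ts.data, dtype=float), fs, f_6db)
        start = int(round((window[0] - ts.times[0]) * fs))
        y = y[start:start + times.size]
        bsel = (times >= baseline[0]) & (times < baseline[1])
        y = y - y[bsel].mean()
        filtered.append(y)
        w1 = (times >= ERFComponents.C1_WINDOW[0]) & (times <= ERFComponents.C1_WINDOW[1])
        w2 = (times >= ERFComponents.C2_WINDOW[0]) & (times <= ERFComponents.C2_WINDOW[1])
        c1.append(np.abs(y[w1]).mean())
        c2.append(np.abs(y[w2]).mean())
        ids.append(ts.meta.get("trial"))
    comp = ERFComponents(np.asarray(c1), np.asarray(c2), np.asarray(ids))
    return times, np.mean(filtered, axis=0), comp
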
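"""Pupil preprocessing with the light-reflex constriction metric, and
velocity-threshold microsaccade detection.

Pupil traces are z-scored within subject, baselined to the last 300 ms
before stimulus onset, and cleaned by replacing samples deviating more than
1.5 raw MAD from a 250 ms running median with linear interpolation; both
eyes are averaged when present. Constriction is the baseline mean minus the
0.5-1.2 s post-stimulus mean (positive = constriction).

Microsaccades are detected with the velocity-threshold method of Engbert &
Kliegl: velocities from a 5-point moving difference, per-dimension
thresholds at lambda times a median-based velocity SD, events as runs of
samples outside the elliptic criterion lasting at least a minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PupilTrace",
    "SaccadeEvent",
    "zscore_subject",
    "running_median",
    "replace_outliers_mad",
    "preprocess_pupil",
    "constriction",
    "detect_microsaccades",
]


@dataclass
class PupilTrace:
    """Preprocessed pupil trace in within-subject z-units, stimulus-aligned."""

    times: np.ndarray
    samples: np.ndarray
    fs: float
    eye: str = "mean"


@dataclass
class SaccadeEvent:
    onset: float
    offset: float
    peak_velocity: float
    amplitude: float

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def zscore_subject(traces: list[np.ndarray]):
    """Z-score a subject's pupil samples using the pooled mean and SD over
    all of that subject's trials."""
    pooled = np.concatenate([np.ravel(t) for t in traces])
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0:
        raise ValueError("constant pupil data: z-score undefined")
    return [(np.asarray(t, float) - mu) / sd for t in traces]


def running_median(x: np.ndarray, width: int) -> np.ndarray:
    """Centered running median, window truncated at the edges."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    half_lo = (width - 1) // 2
    half_hi = width // 2
    for i in range(n):
        out[i] = np.median(x[max(0, i - half_lo):min(n, i + half_hi + 1)])
    return out


def replace_outliers_mad(x: np.ndarray, fs: float, mad_thresh: float = 1.5,
                         median_window_s: float = 0.25,
                         normal_consistency: bool = False) -> np.ndarray:
    """Replace samples deviating more than ``mad_thresh`` MAD from a running
    median by linear interpolation.

    MAD is the raw median absolute deviation of the trace around the running
    median (set ``normal_consistency`` to scale by 1.4826). Outliers at the
    edges are filled from the nearest valid sample. Idempotent: replaced
    samples lie on the interpolation line and are no longer outliers.
    """
    x = np.asarray(x, dtype=float).copy()
    width = max(1, int(round(median_window_s * fs)))
    med = running_median(x, width)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if normal_consistency:
        mad *= 1.4826
    if mad == 0:
        return x
    bad = dev > mad_thresh * mad
    if bad.all():
        raise ValueError("all samples flagged as outliers")
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def preprocess_pupil(times: np.ndarray, traces_by_eye: dict,
                     fs: float, subject_stats: tuple[float, float] | None = None,
                     baseline_window: tuple[float, float] = (-0.3, 0.0),
                     mad_thresh: float = 1.5,
                     median_window_s: float = 0.25) -> PupilTrace:
    """Preprocess one trial's pupil recording.

    ``traces_by_eye`` maps 'left'/'right' (one or both) to raw sample
    arrays. Order of operations: z-score (using ``subject_stats`` = (mean,
    sd) pooled over the subject's session, or this trial when absent) ->
    subtract the per-trial mean of the last 300 ms pre-stimulus -> MAD-based
    outlier replacement per eye -> average eyes when both present.
    """
    times = np.asarray(times, dtype=float)
    if not traces_by_eye:
        raise ValueError("no eye traces provided")
    bsel = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not bsel.any():
        raise ValueError("baseline window not covered by the trace")
    cleaned = []
    for eye, raw in sorted(traces_by_eye.items()):
        x = np.asarray(raw, dtype=float)
        if subject_stats is not None:
            mu, sd = subject_stats
        else:
            mu, sd = x.mean(), x.std()
        if sd == 0:
            sd = 1.0
        x = (x - mu) / sd
        x = x - x[bsel].mean()
        x = replace_outliers_mad(x, fs, mad_thresh=mad_thresh,
                                 median_window_s=median_window_s)
        cleaned.append(x)
    eye = "mean" if len(cleaned) == 2 else next(iter(sorted(traces_by_eye)))
    return PupilTrace(times=times, samples=np.mean(cleaned, axis=0), fs=fs,
                      eye=eye)


def constriction(trace: PupilTrace,
                 baseline_window: tuple[float, float] = (-0.3, 0.0),
                 post_window: tuple[float, float] = (0.5, 1.2)) -> float:
    """Pupil constriction: baseline mean minus post-stimulus-window mean
    (positive values = constriction). Invariant to adding a constant."""
    t = trace.times
    b = (t >= baseline_window[0]) & (t < baseline_window[1])
    p = (t >= post_window[0]) & (t < post_window[1])
    if not b.any() or not p.any():
        raise ValueError("metric windows not covered by the trace")
    return float(trace.samples[b].mean() - trace.samples[p].mean())


def _velocity(pos: np.ndarray, fs: float) -> np.ndarray:
    """5-point moving-difference velocity (deg/s), edges one-sided."""
    n = pos.shape[0]
    v = np.zeros_like(pos)
    if n >= 5:
        v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * (fs / 6.0)
    v[:2] = v[2] if n >= 5 else 0.0
    v[-2:] = v[-3] if n >= 5 else 0.0
    return v


def detect_microsaccades(x: np.ndarray, y: np.ndarray, fs: float,
                         lambda_thresh: float = 6.0,
                         min_dur: float = 0.006):
    """Engbert-Kliegl velocity-threshold microsaccade detection.

    Gaze must be in degrees with fs >= 250 Hz. Thresholds are
    lambda_thresh * sigma per dimension with the median-based estimator
    sigma = sqrt(median(v^2) - median(v)^2); an event is a run of samples
    with (vx/etax)^2 + (vy/etay)^2 > 1 lasting at least ``min_dur``.
    Returns (events, rate) with rate = events per second of trace.
    """
    if fs < 250:
        raise ValueError("sampling rate must be >= 250 Hz")
    pos = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    v = _velocity(pos, fs)
    med = np.median(v, axis=0)
    sigma2 = np.median(v ** 2, axis=0) - med ** 2
    if np.any(sigma2 <= 0):
        raise ValueError("degenerate velocity spread (sigma = 0); "
                         "trace too short or constant")
    eta = lambda_thresh * np.sqrt(sigma2)
    crit = ((v[:, 0] / eta[0]) ** 2 + (v[:, 1] / eta[1]) ** 2) > 1.0
    min_samples = max(1, int(round(min_dur * fs)))
    events = []
    n = crit.size
    i = 0
    while i < n:
        if crit[i]:
            j = i
            while j + 1 < n and crit[j + 1]:
                j += 1
            if j - i + 1 >= min_samples:
                speed = np.linalg.norm(v[i:j + 1], axis=1)
                amp = float(np.linalg.norm(pos[j] - pos[i]))
                events.append(SaccadeEvent(
                    onset=i / fs, offset=(j + 1) / fs,
                    peak_velocity=float(speed.max()), amplitude=amp))
            i = j + 1
        else:
            i += 1
    duration = n / fs
    return events, len(events) / duration
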
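"""Repetition-trajectory modelling.

Per-trial measures are averaged per repetition over the four non-repeated
blocks, z-scored within each subject and averaged over subjects; the cohort
trajectory is then smoothed and fitted either with a continuous broken line
(grid-searched breakpoint separating the early decrease from the late
increase) or with the sum of an exponential decay and a linear trend,
y = a*exp(-x/tau) + b*x + c, with x = repetition - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TrajectoryFit",
    "subject_average_trajectory",
    "running_average",
    "broken_line_fit",
    "exp_linear_fit",
    "r2_adjusted",
]


@dataclass
class TrajectoryFit:
    """Result object for trajectory fits.

    Broken-line fits populate breakpoint/slope_early/slope_late; exponential-
    plus-linear fits populate a/tau/b/c. Both report adjusted R^2.
    """

    breakpoint: int | None = None
    slope_early: float | None = None
    slope_late: float | None = None
    a: float | None = None
    tau: float | None = None
    b: float | None = None
    c: float | None = None
    r2_adj: float = np.nan
    n_params: int = 0
    sse: float = np.nan

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.tau is not None:
            return self.a * np.exp(-(np.asarray(x, float) - 1) / self.tau) \
                + self.b * (np.asarray(x, float) - 1) + self.c
        raise ValueError("predict is defined for exponential-plus-linear fits")


def subject_average_trajectory(table, measure: str, blocks=("A", "B", "C", "D")):
    """Cohort repetition trajectory of one measure.

    Averages the per-trial measure per repetition over the given blocks
    (default: the four non-repeated blocks), z-scores the per-repetition
    series within each subject, and averages over subjects. Returns
    (repetitions, cohort_series).
    """
    sub = table[table["block"].isin(blocks)]
    per = (sub.groupby(["subject", "repetition"])[measure]
           .mean().unstack("repetition"))
    vals = per.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        raise ValueError("constant per-subject series: z-score undefined")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return per.columns.to_numpy(dtype=int), z.mean(axis=0)


def running_average(series, width: int) -> np.ndarray:
    """Centered moving mean with the window truncated at the edges.

    Width 1 is the identity. The display series uses width 5; the
    breakpoint path uses width = max(1, round(0.10 * n))."""
    series = np.asarray(series, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    n = series.size
    out = np.empty(n)
    half_lo = (width - 1) // 2
    half_hi = width // 2
    for i in range(n):
        a = max(0, i - half_lo)
        b = min(n, i + half_hi + 1)
        out[i] = series[a:b].mean()
    return out


def smoothing_width(n: int, frac: float = 0.10) -> int:
    return max(1, int(round(frac * n)))


def broken_line_fit(series, grid=None, x=None, continuous: bool = True) -> TrajectoryFit:
    """Continuous two-segment least-squares fit with grid-searched breakpoint.

    For each candidate k the model is fitted with segment 1 covering x <= k
    and segment 2 covering x >= k (continuous at the breakpoint by default;
    set ``continuous=False`` for two independent lines). Returns the
    breakpoint minimizing total SSE; ties break to the smaller k.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    x = np.arange(1, n + 1, dtype=float) if x is None else np.asarray(x, float)
    if grid is None:
        grid = np.arange(3, min(41, n - 2))
    grid = np.asarray(grid, dtype=int)
    if n <= grid.max() + 2:
        raise ValueError("series too short for the breakpoint grid")
    best = None
    for k in grid:
        if continuous:
            # y = b0 + b1*x + b2*(x-k)_+ : slope_early=b1, slope_late=b1+b2
            X = np.column_stack([np.ones(n), x, np.maximum(x - k, 0.0)])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred = X @ coef
            sse = float(np.sum((y - pred) ** 2))
            s1, s2 = coef[1], coef[1] + coef[2]
        else:
            m1 = x <= k
            m2 = x >= k
            c1 = np.polyfit(x[m1], y[m1], 1)
            c2 = np.polyfit(x[m2], y[m2], 1)
            sse = float(np.sum((y[m1] - np.polyval(c1, x[m1])) ** 2)
                        + np.sum((y[m2] - np.polyval(c2, x[m2])) ** 2))
            s1, s2 = c1[0], c2[0]
            pred = None
        if best is None or sse < best[0] - 1e-12:
            best = (sse, int(k), float(s1), float(s2))
    sse, k, s1, s2 = best
    n_params = 3 if continuous else 4
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return TrajectoryFit(breakpoint=k, slope_early=s1, slope_late=s2,
                         r2_adj=_adjust(r2, n, n_params), n_params=n_params,
                         sse=sse)


def _exp_lin(x, a, tau, b, c):
    return a * np.exp(-x / tau) + b * x + c


def exp_linear_fit(series, x=None,
                   tau_starts=(2.0, 5.0, 10.0, 20.0)) -> TrajectoryFit:
    """Nonlinear least squares of y = a*exp(-x/tau) + b*x + c.

    x is repetition - 1, so ``a`` is the early-decay amplitude at the first
    repetition. Multi-start over tau in ``tau_starts``; the best-SSE
    converged start wins. Raises RuntimeError when no start converges.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 points")
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, float)
    yr = y.max() - y.min()
    best = None
    for tau0 in tau_starts:
        p0 = (max(yr, 1e-6), tau0, (y[-1] - y[n // 2]) / max(x[-1] - x[n // 2], 1.0),
              float(y[-1]))
        try:
            popt, _ = curve_fit(_exp_lin, x, y, p0=p0,
                                bounds=([0.0, 1e-3, -np.inf, -np.inf],
                                        [np.inf, 1e3, np.inf, np.inf]),
                                maxfev=10000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _exp_lin(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("exponential-plus-linear fit did not converge "
                           "from any start")
    sse, (a, tau, b, c) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return TrajectoryFit(a=float(a), tau=float(tau), b=float(b), c=float(c),
                         r2_adj=_adjust(r2, n, 4), n_params=4, sse=sse)


def _adjust(r2: float, n: int, n_params: int) -> float:
    if n - n_params - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def r2_adjusted(y, yhat, n_params: int) -> float:
    """Adjusted R^2: 1 - (1-R^2)(n-1)/(n-n_params-1)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant response: R^2 undefined")
    return _adjust(1.0 - sse / sst, y.size, n_params)
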
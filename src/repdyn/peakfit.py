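"""1/f removal, subject-level band-peak determination, and the per-trial
gamma peak-frequency estimator.

The subject-level procedure fits and subtracts a straight line to the
semilog (log10 power vs linear frequency) average induced-power spectrum,
then fits one Gaussian per canonical band window to the residual. A band
peak is accepted when the Gaussian has positive amplitude and an interior
location; theta/alpha/beta fall back to representative cohort peaks
(6/10/20 Hz), while a missing gamma peak is an error — the estimator must
find one for every subject. The per-trial estimator fits a single Gaussian
directly to the raw per-trial power-change spectrum (single-trial spectra
are too noisy for the full 1/f procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .spectral import PowerChangeSpectrum

__all__ = [
    "BandPeak",
    "GammaPeakNotFoundError",
    "BAND_WINDOWS",
    "FALLBACK_PEAKS",
    "remove_one_over_f",
    "find_band_peaks",
    "trial_gamma_peak",
]

# conventional band search windows (Hz)
BAND_WINDOWS = {
    "theta": (3.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 90.0),
}

FALLBACK_PEAKS = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}


class GammaPeakNotFoundError(RuntimeError):
    """Raised when no positive-amplitude gamma peak can be fitted."""


@dataclass
class BandPeak:
    band: str
    peak_freq: float
    amplitude: float
    width: float
    fallback_used: bool = False


def _gauss(f, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((f - mu) / sigma) ** 2)


def _gauss_offset(f, amp, mu, sigma, c):
    return _gauss(f, amp, mu, sigma) + c


def remove_one_over_f(freqs, power, fit_range=(2.0, 120.0), exclude=None):
    """Residual of a straight-line fit to the semilog power spectrum.

    The line is least-squares fitted to log10(power) against linear
    frequency over ``fit_range`` (optionally excluding a band window, e.g.
    the band about to be fitted) and subtracted everywhere. Returns the
    residual log10-power on the full input grid.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power values must be positive for the semilog fit")
    logp = np.log10(power)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    if exclude is not None:
        sel &= ~((freqs >= exclude[0]) & (freqs <= exclude[1]))
    if sel.sum() < 3:
        raise ValueError("too few frequencies for the 1/f fit")
    slope, intercept = np.polyfit(freqs[sel], logp[sel], 1)
    return logp - (slope * freqs + intercept)


def _fit_gaussian(f, y, window, width_bounds=(1.0, 40.0)):
    """Bounded Gaussian fit within a band window; returns (amp, mu, sigma,
    sse) or None on failure. Initialized at the residual maximum."""
    sel = (f >= window[0]) & (f <= window[1])
    fw, yw = f[sel], y[sel]
    if fw.size < 4:
        return None
    i = int(np.argmax(yw))
    p0 = (max(yw[i], 1e-6), fw[i], 5.0)
    bounds = ([-np.inf, window[0], width_bounds[0]],
              [np.inf, window[1], width_bounds[1]])
    try:
        popt, _ = curve_fit(_gauss, fw, yw, p0=p0, bounds=bounds, maxfev=5000)
    except RuntimeError:
        return None
    sse = float(np.sum((yw - _gauss(fw, *popt)) ** 2))
    return (*popt, sse)


def find_band_peaks(avg_change: PowerChangeSpectrum,
                    bands: dict | None = None,
                    fit_range=(2.0, 120.0)) -> list[BandPeak]:
    """Subject-level band peaks from the average induced power-change
    spectrum.

    Per band, the 1/f-removed spectrum (line fitted excluding that band's
    window) is fitted with a Gaussian inside the search window. Fits with
    non-positive amplitude or an edge location fall back to the
    representative cohort peaks for theta/alpha/beta; a failed gamma fit
    raises GammaPeakNotFoundError.
    """
    bands = bands or BAND_WINDOWS
    f = avg_change.freqs
    out = []
    for band, window in bands.items():
        resid = remove_one_over_f(f, avg_change.change, fit_range=fit_range,
                                  exclude=window)
        fit = _fit_gaussian(f, resid, window)
        ok = fit is not None and fit[0] > 0 and window[0] < fit[1] < window[1]
        if ok:
            out.append(BandPeak(band, float(fit[1]), float(fit[0]),
                                float(fit[2]), fallback_used=False))
        elif band == "gamma":
            raise GammaPeakNotFoundError(
                "no positive-amplitude gamma peak found in 30-90 Hz")
        else:
            out.append(BandPeak(band, FALLBACK_PEAKS[band], np.nan, np.nan,
                                fallback_used=True))
    return out


def trial_gamma_peak(change: PowerChangeSpectrum,
                     accept_range=(2.0, 120.0)) -> float | None:
    """Per-trial gamma peak frequency.

    A single Gaussian plus offset is fitted to the raw change spectrum; the
    location is returned iff the amplitude is positive and the location lies
    inside ``accept_range``; otherwise None (the trial is excluded from
    frequency analyses).
    """
    f = change.freqs
    y = change.change
    med = float(np.median(y))
    i_hi = int(np.argmax(y))
    i_lo = int(np.argmin(y))
    best = None
    # two unconstrained starts (enhancement and suppression) so the sign of
    # the globally best Gaussian decides acceptance
    for p0 in ((max(y[i_hi] - med, 1e-6), f[i_hi], 5.0, med),
               (min(y[i_lo] - med, -1e-6), f[i_lo], 5.0, med)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_gauss_offset, f, y, p0=p0, method="lm",
                                    maxfev=5000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - _gauss_offset(f, *popt)) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, popt)
    if best is None:
        return None
    amp, mu = best[1][0], best[1][1]
    if amp > 0 and accept_range[0] < mu < accept_range[1]:
        return float(mu)
    return None
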
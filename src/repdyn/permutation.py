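"""Shared inferential machinery: sign-flip permutation engines, t_max
familywise correction, subject-level bootstrap, and Spearman correlation.

All permutation and bootstrap engines take an explicit seed (or Generator)
and are reproducible; p-values use the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm) and are therefore never 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "paired_t",
    "sign_flip_null",
    "tmax_correct",
    "permutation_test_1samp",
    "bootstrap_ci",
    "spearman",
]


@dataclass
class PermutationResult:
    """Result of a sign-flip permutation test.

    Attributes
    ----------
    observed : ndarray
        Observed statistic(s), one per tested element.
    p : ndarray
        Corrected p-value per element, in (0, 1].
    n_permutations : int
        Number of permutations actually used (may be the exhaustive count).
    exhaustive : bool
        True if all sign patterns were enumerated.
    seed : int | None
        Seed used for Monte Carlo permutations (None when exhaustive).
    """

    observed: np.ndarray
    p: np.ndarray
    n_permutations: int
    exhaustive: bool = False
    seed: int | None = None
    null_max: np.ndarray = field(default=None, repr=False)


def paired_t(data: np.ndarray) -> np.ndarray:
    """One-sample t statistic per column of a (subjects x elements) matrix."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if n < 2:
        raise ValueError("t statistic needs at least 2 subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)


def _sign_matrix(n_subjects: int, n_perm: int, rng: np.random.Generator,
                 max_exhaustive: int = 12):
    """Sign-flip patterns: exhaustive when 2**n_subjects <= 2**max_exhaustive,
    otherwise ``n_perm`` random draws. Returns (signs, exhaustive)."""
    if n_subjects <= max_exhaustive and 2 ** n_subjects <= max(n_perm, 2 ** max_exhaustive):
        bits = np.arange(2 ** n_subjects, dtype=np.uint32)
        signs = np.where(
            (bits[:, None] >> np.arange(n_subjects)) & 1, 1.0, -1.0
        )
        return signs, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    return signs, False


def sign_flip_null(data: np.ndarray, n_perm: int, rng: np.random.Generator,
                   max_exhaustive: int = 12):
    """Null distribution of per-element t statistics under sign flipping.

    Returns (null_t, exhaustive) where null_t has shape (n_perm, n_elements).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, _ = data.shape
    signs, exhaustive = _sign_matrix(n, n_perm, rng, max_exhaustive)
    flipped_mean = signs @ data / n
    # per-permutation sd: E[x^2] is flip-invariant
    sq_mean = (data ** 2).mean(axis=0)
    var = (sq_mean[None, :] - flipped_mean ** 2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        null_t = flipped_mean / np.sqrt(var / n)
    null_t[~np.isfinite(null_t)] = 0.0
    return null_t, exhaustive


def tmax_correct(data: np.ndarray, n_perm: int = 1000, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> PermutationResult:
    """t_max familywise correction for one-sample tests across elements.

    Subject rows of ``data`` (subjects x elements) are sign-flipped; the
    maximum |t| across elements per permutation forms the null. Two-tailed.
    Sign patterns are enumerated exhaustively for <= 12 subjects.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("tmax_correct needs >= 2 subjects")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = paired_t(data)
    null_t, exhaustive = sign_flip_null(data, n_perm, rng)
    null_max = np.abs(null_t).max(axis=1)
    n_eff = null_max.shape[0]
    p = (1.0 + (null_max[:, None] >= np.abs(observed)[None, :]).sum(axis=0)) / (1.0 + n_eff)
    p = np.minimum(p, 1.0)
    return PermutationResult(observed=observed, p=p, n_permutations=n_eff,
                             exhaustive=exhaustive, seed=seed, null_max=null_max)


def permutation_test_1samp(values: np.ndarray, n_perm: int = 1000,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> PermutationResult:
    """Two-tailed sign-flip permutation test of a single mean against zero."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    return tmax_correct(values, n_perm=n_perm, seed=seed, rng=rng)


def bootstrap_ci(data, statistic, n_boot: int = 1000, seed: int | None = None,
                 rng: np.random.Generator | None = None, alpha: float = 0.05):
    """Percentile bootstrap CI with resampling at the first-axis unit level.

    ``data`` is an array (units x ...) or a sequence of per-unit objects;
    ``statistic`` maps a resampled collection to a scalar or vector.
    Returns (lo, hi) arrays and the bootstrap replicate matrix.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(data)
    is_array = isinstance(data, np.ndarray)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data[idx] if is_array else [data[i] for i in idx]
        reps.append(np.asarray(statistic(sample), dtype=float))
    reps = np.asarray(reps)
    lo = np.percentile(reps, 100 * alpha / 2, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha / 2), axis=0)
    return lo, hi, reps


def _spearman_exact_p(x_rank: np.ndarray, y_rank: np.ndarray, rho: float) -> float:
    """Exhaustive two-tailed permutation p for Spearman rho (n <= 9)."""
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (yc[perms] @ xc) / denom
    obs = abs(rho)
    return (np.abs(rhos) >= obs - 1e-12).mean()


def spearman(x, y, seed: int = 0, n_mc: int = 20000):
    """Spearman rank correlation with small-sample permutation p-values.

    Ties are handled by midranks. For n <= 9 the permutation null is
    enumerated exactly; for 10 <= n <= 12 a seeded Monte Carlo permutation
    p is used; larger samples use the asymptotic t approximation.
    Returns (rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = np.corrcoef(xr, yr)[0, 1]
    if n <= 9:
        p = _spearman_exact_p(xr, yr, rho)
    elif n <= 12:
        rng = np.random.default_rng(seed)
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        count = 0
        for _ in range(n_mc):
            rhos = (yc[rng.permutation(n)] @ xc) / denom
            count += abs(rhos) >= abs(rho) - 1e-12
        p = (1 + count) / (1 + n_mc)
    else:
        p = sps.spearmanr(x, y).pvalue
    return float(rho), float(p)
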
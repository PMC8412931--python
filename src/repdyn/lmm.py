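"""Hierarchical regression of per-trial measures with crossed random
intercepts for subject and stimulus orientation.

The model for a per-trial response y is

    y = b0 + Subject0 + Orientation0 + b1*repetition + b2*trial
        + b3*repeat_block + b4*ITI + b5*microsaccade_rate
        + b6*pupil_constriction + b7*early_repetition + e

with Subject0 ~ N(0, var_subject), Orientation0 ~ N(0, var_orientation)
crossed, estimated by REML. Inference uses t statistics with Satterthwaite
degrees of freedom plus subject-level case-bootstrap percentile confidence
intervals; an effect counts as significant only when the Satterthwaite p is
below alpha AND the bootstrap CI excludes zero (the dual gate guards against
the approximation being anticonservative).

The two-variance-component REML surface is evaluated directly through the
Woodbury identity on sufficient statistics, which makes single fits cheap
enough for bootstrap and simulation studies; R's lmerTest serves as an
independent cross-check in the test suite.

The early-repetition term has two encodings: a ramp min(repetition, 10)
fitted jointly with the full repetition regressor (default; the drop over
the first ten presentations attributable to the early term is then
-9*b_early, while b1 carries the steady per-repetition trend), or a pure
first-ten indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import t as t_dist

__all__ = [
    "LMMSpec",
    "Design",
    "CrossedLMM",
    "CrossedLMMResults",
    "build_design",
    "fit_lmm",
    "per_subject_slopes",
    "correlate_slopes",
]

_COVARIATES = ["repetition", "trial", "repetition_block", "iti_s",
               "ms_rate", "pupil_constriction", "early_repetition"]

_COLUMN_SOURCES = {
    "repetition": "repetition",
    "trial": "trial",
    "iti_s": "iti_s",
    "ms_rate": "ms_rate",
    "pupil_constriction": "pupil_constriction",
}


@dataclass
class LMMSpec:
    """Model specification: response, covariates and drop rules.

    When the response is itself one of the covariates it is removed from
    the independent variables; for pupil analyses the repeat-block term is
    dropped as well (the first block and its repeat are excluded from pupil
    data). ``early_encoding`` selects the ramp (default) or indicator form
    of the first-ten-repetitions term.
    """

    response: str = "gamma_power"
    early_encoding: str = "ramp"
    extra_drop: tuple = ()

    def dropped(self) -> set:
        drop = set(self.extra_drop)
        if self.response == "pupil_constriction":
            drop |= {"pupil_constriction", "repetition_block"}
        if self.response == "ms_rate":
            drop.add("ms_rate")
        drop.discard("")
        return drop


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    names: list
    subject: np.ndarray      # integer codes 0..S-1
    orientation: np.ndarray  # integer codes 0..O-1
    subject_levels: np.ndarray
    orientation_levels: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size


def _early_column(rep: np.ndarray, encoding: str) -> np.ndarray:
    if encoding == "ramp":
        return np.minimum(rep, 10.0)
    if encoding == "indicator":
        return (rep <= 10).astype(float)
    raise ValueError(f"unknown early_repetition encoding {encoding!r}")


def build_design(table: pd.DataFrame, spec: LMMSpec) -> Design:
    """Numeric design matrix from a per-trial table.

    Requires columns subject, block, orientation, repetition, trial plus the
    covariates not dropped by the spec. Categorical terms (repeat block) are
    indicator-coded; artifact/catch trials must be excluded upstream.
    """
    required = {"subject", "block", "orientation", "repetition", "trial"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if spec.response not in table.columns:
        raise ValueError(f"response column {spec.response!r} not in table")
    drop = spec.dropped()
    rep = table["repetition"].to_numpy(float)
    cols, names = [np.ones(len(table))], ["intercept"]
    for name in _COVARIATES:
        if name in drop:
            continue
        if name == "repetition_block":
            cols.append((table["block"] == "A2").to_numpy(float))
        elif name == "early_repetition":
            cols.append(_early_column(rep, spec.early_encoding))
        else:
            src = _COLUMN_SOURCES[name]
            if src == spec.response:
                continue
            if src not in table.columns:
                raise ValueError(f"missing covariate column {src!r}")
            cols.append(table[src].to_numpy(float))
        names.append(name)
    X = np.column_stack(cols)
    y = table[spec.response].to_numpy(float)
    subj_levels, subj = np.unique(table["subject"].to_numpy(), return_inverse=True)
    ori_levels, ori = np.unique(table["orientation"].to_numpy(), return_inverse=True)
    return Design(y=y, X=X, names=names, subject=subj, orientation=ori,
                  subject_levels=subj_levels, orientation_levels=ori_levels)


class _Suff:
    """Sufficient statistics for the two-crossed-intercept REML surface."""

    def __init__(self, design: Design):
        y, X = design.y, design.X
        S = design.subject_levels.size
        O = design.orientation_levels.size
        n, p = X.shape
        q = S + O
        Z_idx_s = design.subject
        Z_idx_o = S + design.orientation
        ZtZ = np.zeros((q, q))
        np.add.at(ZtZ, (Z_idx_s, Z_idx_s), 1.0)
        np.add.at(ZtZ, (Z_idx_o, Z_idx_o), 1.0)
        np.add.at(ZtZ, (Z_idx_s, Z_idx_o), 1.0)
        np.add.at(ZtZ, (Z_idx_o, Z_idx_s), 1.0)
        ZtX = np.zeros((q, p))
        np.add.at(ZtX, Z_idx_s, X)
        np.add.at(ZtX, Z_idx_o, X)
        Zty = np.zeros(q)
        np.add.at(Zty, Z_idx_s, y)
        np.add.at(Zty, Z_idx_o, y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ, self.ZtX, self.Zty = ZtZ, ZtX, Zty
        self.n, self.p, self.S, self.O, self.q = n, p, S, O, q

    def _whitened(self, gam_s: float, gam_o: float):
        g = np.concatenate([np.full(self.S, gam_s), np.full(self.O, gam_o)])
        sg = np.sqrt(np.maximum(g, 0.0))
        A = np.eye(self.q) + (sg[:, None] * self.ZtZ) * sg[None, :]
        cf = cho_factor(A, lower=True)
        logdet_A = 2.0 * np.log(np.diag(cf[0])).sum()
        U = sg[:, None] * self.ZtX
        uy = sg * self.Zty
        AiU = cho_solve(cf, U)
        Aiuy = cho_solve(cf, uy)
        XtWX = self.XtX - U.T @ AiU
        XtWy = self.Xty - U.T @ Aiuy
        ytWy = self.yty - uy @ Aiuy
        return XtWX, XtWy, ytWy, logdet_A

    def profiled_neg2reml(self, log_gammas: np.ndarray) -> float:
        gam_s, gam_o = np.exp(log_gammas)
        XtWX, XtWy, ytWy, logdet_A = self._whitened(gam_s, gam_o)
        sign, logdet_X = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, np.finfo(float).tiny)
        return (self.n - self.p) * math.log(rss) + logdet_A + logdet_X

    def beta_cov(self, gam_s: float, gam_o: float):
        """GLS beta, its covariance factor (X'W^-1 X)^-1, and sigma^2."""
        XtWX, XtWy, ytWy, _ = self._whitened(gam_s, gam_o)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, 0.0)
        sigma2 = rss / (self.n - self.p)
        cov_unscaled = np.linalg.inv(XtWX)
        return beta, cov_unscaled, sigma2

    def neg2reml_theta(self, theta: np.ndarray) -> float:
        """-2 REML log-likelihood in the variance parametrization
        theta = (var_subject, var_orientation, var_residual)."""
        vs, vo, ve = theta
        if ve <= 0 or vs < 0 or vo < 0:
            return np.inf
        XtWX, XtWy, ytWy, logdet_A = self._whitened(vs / ve, vo / ve)
        sign, logdet_X = np.linalg.slogdet(XtWX / ve)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - beta @ XtWy, np.finfo(float).tiny)
        return (self.n * math.log(ve) + logdet_A) + logdet_X + rss / ve

    def coef_var_theta(self, theta: np.ndarray, j: int) -> float:
        """Var(beta_j) as a function of the variance parameters."""
        vs, vo, ve = theta
        XtWX, _, _, _ = self._whitened(vs / ve, vo / ve)
        return float(np.linalg.inv(XtWX)[j, j] * ve)


@dataclass
class CrossedLMMResults:
    """REML estimates with Satterthwaite and bootstrap inference."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    var_subject: float
    var_orientation: float
    var_residual: float
    df: np.ndarray
    satterthwaite_p: np.ndarray
    converged: bool
    singular: bool
    n_obs: int
    boot_ci95: np.ndarray | None = None   # (p, 2)
    n_boot: int = 0
    model: "CrossedLMM | None" = field(default=None, repr=False)

    @property
    def tvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def dual_significant(self) -> np.ndarray:
        """Satterthwaite p < 0.05 AND bootstrap CI95 excludes zero."""
        if self.boot_ci95 is None:
            raise ValueError("bootstrap CIs not computed; call "
                             "fit(n_boot=...) or bootstrap_ci()")
        ci_excl = (self.boot_ci95[:, 0] > 0) | (self.boot_ci95[:, 1] < 0)
        return (self.satterthwaite_p < 0.05) & ci_excl

    def coef_table(self) -> pd.DataFrame:
        d = {"coef": self.beta, "se": self.se, "t": self.tvalues,
             "df": self.df, "p_satterthwaite": self.satterthwaite_p}
        if self.boot_ci95 is not None:
            d["ci_lo"] = self.boot_ci95[:, 0]
            d["ci_hi"] = self.boot_ci95[:, 1]
            d["dual_significant"] = self.dual_significant
        return pd.DataFrame(d, index=self.names)

    def summary(self) -> str:
        lines = [
            "Crossed random-intercept LMM (REML)",
            f"n_obs = {self.n_obs}   converged = {self.converged}"
            f"   singular = {self.singular}",
            f"var(subject) = {self.var_subject:.4g}   "
            f"var(orientation) = {self.var_orientation:.4g}   "
            f"var(residual) = {self.var_residual:.4g}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)


class CrossedLMM:
    """Linear mixed model with crossed subject and orientation intercepts.

    Build from a Design (see build_design) or via from_dataframe; fit()
    returns a CrossedLMMResults.
    """

    BOUNDARY = 1e-8  # variance ratio below which a component counts as zero

    def __init__(self, design: Design):
        if design.subject_levels.size < 2:
            raise ValueError("need >= 2 subjects")
        if design.orientation_levels.size < 2:
            raise ValueError("need >= 2 orientations")
        self.design = design
        self._suff = _Suff(design)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame,
                       spec: LMMSpec | None = None, **spec_kw) -> "CrossedLMM":
        spec = spec or LMMSpec(**spec_kw)
        return cls(build_design(table, spec))

    def fit(self, n_boot: int = 0, seed: int | None = None) -> CrossedLMMResults:
        s = self._suff
        res = optimize.minimize(
            s.profiled_neg2reml, x0=np.log([0.1, 0.1]),
            method="L-BFGS-B", bounds=[(-25.0, 12.0)] * 2)
        gam_s, gam_o = np.exp(res.x)
        beta, cov_u, sigma2 = s.beta_cov(gam_s, gam_o)
        se = np.sqrt(np.diag(cov_u) * sigma2)
        theta = np.array([gam_s * sigma2, gam_o * sigma2, sigma2])
        singular = bool(gam_s < self.BOUNDARY or gam_o < self.BOUNDARY)
        df = np.array([self._satterthwaite_df(theta, j)
                       for j in range(beta.size)])
        p = 2.0 * t_dist.sf(np.abs(beta / se), df)
        result = CrossedLMMResults(
            beta=beta, se=se, names=list(self.design.names),
            var_subject=float(theta[0]), var_orientation=float(theta[1]),
            var_residual=float(theta[2]), df=df, satterthwaite_p=p,
            converged=bool(res.success), singular=singular,
            n_obs=s.n, model=self)
        if n_boot > 0:
            result.boot_ci95 = self.bootstrap_ci(n_boot=n_boot, seed=seed)
            result.n_boot = n_boot
        return result

    # -- Satterthwaite ------------------------------------------------------
    def _satterthwaite_df(self, theta: np.ndarray, j: int) -> float:
        s = self._suff
        free = [k for k in range(2) if theta[k] / theta[2] >= self.BOUNDARY] + [2]
        if len(free) == 1:
            return float(s.n - s.p)

        def pack(th_free):
            th = theta.copy()
            th[free] = th_free
            return th

        th0 = theta[free]
        scale = np.maximum(np.abs(th0), 1e-10)
        h = 1e-4 * scale

        def C(th_free):
            return s.coef_var_theta(pack(th_free), j)

        def L(th_free):
            return s.neg2reml_theta(pack(th_free))

        grad = np.array([
            (C(th0 + h * _e(i, len(free))) - C(th0 - h * _e(i, len(free))))
            / (2 * h[i]) for i in range(len(free))])
        H = _num_hessian(L, th0, h)
        try:
            var_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(s.n - s.p)
        denom = float(grad @ var_theta @ grad)
        c0 = C(th0)
        if denom <= 0 or not np.isfinite(denom):
            return float(s.n - s.p)
        df = 2.0 * c0 ** 2 / denom
        return float(np.clip(df, 1.0, s.n - s.p))

    # -- bootstrap ----------------------------------------------------------
    def bootstrap_ci(self, n_boot: int = 1000, seed: int | None = None,
                     alpha: float = 0.05) -> np.ndarray:
        """Subject-level case bootstrap percentile CIs for the fixed effects.

        Subjects are resampled with replacement and relabeled as distinct
        subjects before refitting (so a twice-drawn subject contributes two
        independent random intercepts)."""
        rng = np.random.default_rng(seed)
        d = self.design
        S = d.subject_levels.size
        by_subject = [np.flatnonzero(d.subject == s) for s in range(S)]
        reps = np.empty((n_boot, d.X.shape[1]))
        for bi in range(n_boot):
            draw = rng.integers(0, S, size=S)
            rows = np.concatenate([by_subject[s] for s in draw])
            new_subj = np.concatenate([
                np.full(by_subject[s].size, k) for k, s in enumerate(draw)])
            bd = Design(y=d.y[rows], X=d.X[rows], names=d.names,
                        subject=new_subj, orientation=d.orientation[rows],
                        subject_levels=np.arange(S),
                        orientation_levels=d.orientation_levels)
            suff = _Suff(bd)
            res = optimize.minimize(
                suff.profiled_neg2reml, x0=np.log([0.1, 0.1]),
                method="L-BFGS-B", bounds=[(-25.0, 12.0)] * 2)
            gs, go = np.exp(res.x)
            beta, _, _ = suff.beta_cov(gs, go)
            reps[bi] = beta
        lo = np.percentile(reps, 100 * alpha / 2, axis=0)
        hi = np.percentile(reps, 100 * (1 - alpha / 2), axis=0)
        return np.column_stack([lo, hi])


def _e(i: int, k: int) -> np.ndarray:
    v = np.zeros(k)
    v[i] = 1.0
    return v


def _num_hessian(f, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    k = x0.size
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for jj in range(i, k):
            if i == jj:
                H[i, i] = (f(x0 + h * _e(i, k)) - 2 * f0
                           + f(x0 - h * _e(i, k))) / h[i] ** 2
            else:
                fpp = f(x0 + h * _e(i, k) + h * _e(jj, k))
                fpm = f(x0 + h * _e(i, k) - h * _e(jj, k))
                fmp = f(x0 - h * _e(i, k) + h * _e(jj, k))
                fmm = f(x0 - h * _e(i, k) - h * _e(jj, k))
                H[i, jj] = H[jj, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[jj])
    return H


def fit_lmm(table: pd.DataFrame, response: str = "gamma_power",
            early_encoding: str = "ramp", n_boot: int = 0,
            seed: int | None = None) -> CrossedLMMResults:
    """Convenience wrapper: build the design for ``response`` and fit."""
    model = CrossedLMM.from_dataframe(table, response=response,
                                      early_encoding=early_encoding)
    return model.fit(n_boot=n_boot, seed=seed)


def per_subject_slopes(table: pd.DataFrame, response: str,
                       splits=(("early", 1, 10), ("late", 11, 120)),
                       min_trials: int = 5) -> pd.DataFrame:
    """Per-subject OLS repetition slopes, separately per repetition split.

    Uses the same covariates as the mixed model minus the random intercepts
    and the early-repetition term (collinear with repetition within a
    split). Subjects with fewer than ``min_trials`` usable trials in a split
    get NaN and usable=False.
    """
    spec = LMMSpec(response=response, extra_drop=("early_repetition",))
    rows = []
    for subject, sub in table.groupby("subject"):
        for name, lo, hi in splits:
            seg = sub[(sub["repetition"] >= lo) & (sub["repetition"] <= hi)]
            if len(seg) < max(min_trials, 3) or seg["repetition"].std() == 0:
                rows.append((subject, name, np.nan, False))
                continue
            d = build_design(seg, spec)
            X, y = d.X, d.y
            keep = [i for i, nm in enumerate(d.names)
                    if nm == "intercept" or X[:, i].std() > 0]
            coef, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
            names = [d.names[i] for i in keep]
            rows.append((subject, name, float(coef[names.index("repetition")]),
                         True))
    return pd.DataFrame(rows, columns=["subject", "split", "slope", "usable"])


def correlate_slopes(slopes_a: pd.Series | np.ndarray,
                     slopes_b: pd.Series | np.ndarray, seed: int = 0):
    """Spearman rank correlation of per-subject slopes across measures."""
    from .permutation import spearman
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return spearman(a[ok], b[ok], seed=seed)
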
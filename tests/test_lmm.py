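"""Crossed random-intercept mixed model: design construction, REML
estimates, Satterthwaite inference, bootstrap CIs and per-subject slopes."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from repdyn import lmm, synth
from repdyn.lmm import (CrossedLMM, LMMSpec, build_design, correlate_slopes,
                        fit_lmm, per_subject_slopes)


def _skeleton(n_subjects=6, trials_per_block=30, seed=0):
    cfg = synth.ExperimentConfig(n_subjects=n_subjects,
                                 trials_per_block=trials_per_block, seed=seed)
    return synth.generate_trial_table(cfg)


def _simulate_from_model(table, beta_map, vs, vo, ve, rng,
                         response="gamma_power"):
    """Simulate the response from the model's own structural form."""
    d = build_design(table, LMMSpec(response=response))
    beta = np.array([beta_map.get(n, 0.0) for n in d.names])
    us = rng.normal(0, np.sqrt(vs), d.subject_levels.size)
    uo = rng.normal(0, np.sqrt(vo), d.orientation_levels.size)
    y = d.X @ beta + us[d.subject] + uo[d.orientation] \
        + rng.normal(0, np.sqrt(ve), d.n)
    out = table.copy()
    out[response] = y
    return out


class TestDesign:
    def test_row_count_and_a2_indicator(self):
        t = _skeleton(2, 120)
        d = build_design(t[t.subject == 1], LMMSpec())
        assert d.X.shape[0] == 600
        a2 = d.X[:, d.names.index("repetition_block")]
        np.testing.assert_array_equal(
            a2, (t[t.subject == 1]["block"] == "A2").to_numpy(float))

    @pytest.mark.parametrize("rep,ramp,indicator", [
        (1, 1.0, 1.0), (7, 7.0, 1.0), (10, 10.0, 1.0),
        (11, 10.0, 0.0), (120, 10.0, 0.0)])
    def test_early_regressor_encoding_truth_table(self, rep, ramp, indicator):
        t = _skeleton(2, 20).iloc[:40].copy()
        t.loc[t.index[0], "repetition"] = rep
        for enc, expected in (("ramp", ramp), ("indicator", indicator)):
            d = build_design(t, LMMSpec(early_encoding=enc))
            assert d.X[0, d.names.index("early_repetition")] == expected

    def test_response_dropped_from_covariates(self):
        t = _skeleton(2, 20)
        d = build_design(t, LMMSpec(response="pupil_constriction"))
        assert "pupil_constriction" not in d.names
        assert "repetition_block" not in d.names
        d2 = build_design(t, LMMSpec(response="ms_rate"))
        assert "ms_rate" not in d2.names

    def test_missing_column_named_in_error(self):
        t = _skeleton(2, 20).drop(columns=["iti_s"])
        with pytest.raises(ValueError, match="iti_s"):
            build_design(t, LMMSpec())


class TestREML:
    def test_ols_degenerate_matches_least_squares(self, rng):
        """With zero true random-effect variance the REML fit collapses to
        OLS: betas within 1e-6 and Satterthwaite df = n - p."""
        t = _skeleton(5, 20, seed=1)
        t = _simulate_from_model(t, {"intercept": 10.0, "repetition": 0.5},
                                 vs=0.0, vo=0.0, ve=4.0, rng=rng)
        model = CrossedLMM.from_dataframe(t, response="gamma_power")
        res = model.fit()
        d = model.design
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(res.beta, ols, atol=1e-6)
        assert res.singular
        n, p = d.X.shape
        np.testing.assert_allclose(res.df, n - p, rtol=1e-6)

    def test_beta1_recovery_low_bias(self, rng):
        betas = []
        for s in range(15):
            t = _skeleton(8, 30, seed=100 + s)
            t = _simulate_from_model(
                t, {"intercept": 50.0, "repetition": 0.4,
                    "early_repetition": -3.0}, vs=400.0, vo=25.0, ve=2500.0,
                rng=rng)
            res = fit_lmm(t, response="gamma_power")
            betas.append(res.beta[res.names.index("repetition")])
        assert abs(np.mean(betas) - 0.4) < 0.1

    def test_variance_components_recovered(self, rng):
        ests = []
        for s in range(10):
            t = _skeleton(12, 40, seed=200 + s)
            t = _simulate_from_model(t, {"intercept": 5.0}, vs=100.0,
                                     vo=16.0, ve=400.0, rng=rng)
            res = fit_lmm(t, response="gamma_power")
            ests.append([res.var_subject, res.var_residual])
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(100.0, rel=0.5)
        assert mean[1] == pytest.approx(400.0, rel=0.05)

    def test_matches_lmer_satterthwaite(self, tmp_path, rng):
        """Independent oracle: R lmerTest on the identical dataset gives the
        same REML betas, SEs, Satterthwaite dfs and p-values."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        t = _skeleton(6, 25, seed=4)
        t = _simulate_from_model(t, {"intercept": 20.0, "repetition": 0.3,
                                     "early_repetition": -2.0},
                                 vs=150.0, vo=40.0, ve=900.0, rng=rng)
        csv = tmp_path / "fixture.csv"
        t.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
d$a2 <- as.numeric(d$block == "A2")
d$early <- pmin(d$repetition, 10)
m <- lmer(gamma_power ~ repetition + trial + a2 + iti_s + ms_rate +
          pupil_constriction + early + (1|subject) + (1|orientation),
          data = d, REML = TRUE)
co <- summary(m)$coefficients
write.csv(co, "{tmp_path}/out.csv")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        res = fit_lmm(t, response="gamma_power")
        mine = res.coef_table()
        order = ["(Intercept)", "repetition", "trial", "a2", "iti_s",
                 "ms_rate", "pupil_constriction", "early"]
        np.testing.assert_allclose(mine["coef"].to_numpy(),
                                   ref.loc[order, "Estimate"].to_numpy(),
                                   rtol=1e-4)
        np.testing.assert_allclose(mine["se"].to_numpy(),
                                   ref.loc[order, "Std. Error"].to_numpy(),
                                   rtol=1e-3)
        np.testing.assert_allclose(mine["df"].to_numpy(),
                                   ref.loc[order, "df"].to_numpy(), rtol=0.02)
        np.testing.assert_allclose(
            mine["p_satterthwaite"].to_numpy(),
            ref.loc[order, "Pr(>|t|)"].to_numpy(), rtol=0.05, atol=1e-12)

    def test_satterthwaite_df_decreases_with_subject_variance(self):
        """On a constructed sequence of datasets with growing between-
        subject variance (same noise realization) the intercept's effective
        df falls from ~n-p toward ~n_subjects - 1."""
        t = _skeleton(6, 25, seed=9)
        rng = np.random.default_rng(0)
        d = build_design(t, LMMSpec(response="gamma_power"))
        us_unit = rng.normal(0, 1, d.subject_levels.size)
        e = rng.normal(0, np.sqrt(500.0), d.n)
        base = d.X @ np.array([10.0] + [0.0] * (d.X.shape[1] - 1))
        dfs = []
        for vs in (10.0, 100.0, 1000.0, 10000.0):
            t2 = t.copy()
            t2["gamma_power"] = base + np.sqrt(vs) * us_unit[d.subject] + e
            res = fit_lmm(t2, response="gamma_power")
            dfs.append(res.df[res.names.index("intercept")])
        assert all(a > b for a, b in zip(dfs, dfs[1:]))
        assert dfs[-1] < 10  # approaches n_subjects - 1

    def test_null_satterthwaite_p_uniform(self):
        """Under beta1 = 0 the Satterthwaite p-values for the repetition
        coefficient are uniform (KS test at alpha = 0.01)."""
        rng = np.random.default_rng(77)
        pvals = []
        for s in range(120):
            t = _skeleton(6, 20, seed=300 + s)
            t = _simulate_from_model(t, {"intercept": 5.0}, vs=50.0, vo=9.0,
                                     ve=200.0, rng=rng)
            res = fit_lmm(t, response="gamma_power")
            pvals.append(res.satterthwaite_p[res.names.index("repetition")])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        t = _skeleton(5, 20, seed=2)
        model = CrossedLMM.from_dataframe(t, response="gamma_power")
        ci1 = model.bootstrap_ci(n_boot=30, seed=5)
        ci2 = model.bootstrap_ci(n_boot=30, seed=5)
        np.testing.assert_array_equal(ci1, ci2)

    def test_near_noiseless_ci_shrinks(self, rng):
        t = _skeleton(6, 20, seed=3)
        t = _simulate_from_model(t, {"intercept": 4.0, "repetition": 0.2},
                                 vs=0.0, vo=0.0, ve=1e-8, rng=rng)
        model = CrossedLMM.from_dataframe(t, response="gamma_power")
        ci = model.bootstrap_ci(n_boot=40, seed=1)
        j = model.design.names.index("repetition")
        assert ci[j, 1] - ci[j, 0] < 1e-4

    def test_dual_significance_definition(self):
        t = _skeleton(6, 30, seed=8)
        res = fit_lmm(t, response="gamma_power", n_boot=50, seed=3)
        ci_excl = (res.boot_ci95[:, 0] > 0) | (res.boot_ci95[:, 1] < 0)
        np.testing.assert_array_equal(
            res.dual_significant, (res.satterthwaite_p < 0.05) & ci_excl)


class TestPerSubjectSlopes:
    def test_identical_subjects_zero_spread(self):
        base = _skeleton(1, 40, seed=5)
        frames = []
        for s in range(1, 5):
            f = base.copy()
            f["subject"] = s
            frames.append(f)
        t = pd.concat(frames, ignore_index=True)
        slopes = per_subject_slopes(t, "gamma_power",
                                    splits=(("early", 1, 10), ("late", 11, 40)))
        for _, grp in slopes.groupby("split"):
            assert grp["slope"].std() == pytest.approx(0.0, abs=1e-10)

    def test_too_few_trials_flagged(self):
        t = _skeleton(2, 20, seed=6)
        t = t[~((t.subject == 1) & (t.repetition <= 9))]
        slopes = per_subject_slopes(t, "gamma_power",
                                    splits=(("early", 1, 10), ("late", 11, 20)))
        row = slopes[(slopes.subject == 1) & (slopes.split == "early")]
        assert not row["usable"].item()
        assert np.isnan(row["slope"].item())

    def test_correlate_slopes_extremes(self):
        a = np.arange(10.0)
        rho, p = correlate_slopes(a, a * 3 + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = correlate_slopes(a, -a)
        assert rho == pytest.approx(-1.0)
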
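"""Nonparametric Granger causality: CSD estimation, Wilson factorization,
directed spectra, permutation statistics and time-reversal validation."""

import numpy as np
import pytest

from repdyn import connectivity as conn, synth
from repdyn.connectivity import (cluster_test_freq, compute_csd, direction_of,
                                 ff_fb_contrast, gc_from_trials,
                                 granger_spectrum, load_hierarchy,
                                 pool_and_average, regress_out_power,
                                 time_reversal_control, time_reverse,
                                 tmax_pairs_test, wilson_factorize)

FS = 1200.0
GAMMA = (40.0, 80.0)


def _analytic_stack(truth, nfreq=601):
    freqs = np.arange(0.0, float(nfreq))
    _, S = synth.var_spectral_matrix(truth.var_coefficients, truth.noise_cov,
                                     freqs, FS)
    return conn.CSDStack(freqs=freqs, csd=S, n_windows=1, fs=FS)


class TestCSD:
    def test_single_channel_equals_power_spectrum(self, rng):
        n = int(2.0 * FS)
        x = rng.normal(size=(1, n))
        trials = [synth.TrialSeries(x, FS, np.arange(n) / FS)]
        stack = compute_csd(trials, window=(0.4, 2.0))
        assert stack.csd.shape[1:] == (1, 1)
        assert np.allclose(stack.csd.imag, 0.0, atol=1e-12)
        assert np.all(stack.csd[1:, 0, 0].real >= 0)

    def test_common_signal_coherence_one(self, rng):
        n = int(2.0 * FS)
        s = rng.normal(size=n)
        trials = [synth.TrialSeries(np.vstack([s, s]), FS, np.arange(n) / FS)]
        stack = compute_csd(trials, window=(0.4, 2.0))
        c = stack.csd
        coh = np.abs(c[5:, 0, 1]) ** 2 / (c[5:, 0, 0].real * c[5:, 1, 1].real)
        assert np.allclose(coh, 1.0, atol=1e-8)

    def test_independent_noise_coherence_vanishes(self, rng):
        trials = []
        n = int(2.0 * FS)
        for _ in range(100):   # ~ 700 windows
            x = rng.normal(size=(2, n))
            trials.append(synth.TrialSeries(x, FS, np.arange(n) / FS))
        stack = compute_csd(trials, window=(0.4, 2.0))
        c = stack.csd
        coh = np.abs(c[5:120, 0, 1]) ** 2 / (c[5:120, 0, 0].real
                                             * c[5:120, 1, 1].real)
        assert np.mean(coh) < 0.05

    def test_no_usable_windows_raises(self):
        n = int(0.3 * FS)
        trials = [synth.TrialSeries(np.zeros((2, n)), FS, np.arange(n) / FS)]
        with pytest.raises(ValueError, match="window"):
            compute_csd(trials, window=(0.4, 2.0))


class TestWilson:
    def test_diagonal_white_csd_identity_transfer(self):
        freqs = np.arange(0.0, 601.0)
        S = np.tile(np.diag([2.0, 5.0]).astype(complex), (601, 1, 1))
        stack = conn.CSDStack(freqs=freqs, csd=S, n_windows=1, fs=FS)
        H, sigma, info = wilson_factorize(stack)
        np.testing.assert_allclose(H, np.tile(np.eye(2), (601, 1, 1)),
                                   atol=1e-7)
        np.testing.assert_allclose(sigma, np.diag([2.0, 5.0]), atol=1e-6)

    def test_roundtrip_residual_below_1e6(self, var_pair):
        stack = _analytic_stack(var_pair)
        H, sigma, info = wilson_factorize(stack, tol=1e-12, max_iter=500)
        S_rec = H @ sigma @ np.conj(np.swapaxes(H, 1, 2))
        rel = np.linalg.norm(S_rec - stack.csd) / np.linalg.norm(stack.csd)
        assert rel < 1e-6

    def test_transfer_and_innovations_match_var(self, var_pair):
        """H and Sigma from the factorization match the generating VAR's
        transfer function and innovation covariance within 1%."""
        stack = _analytic_stack(var_pair)
        H, sigma, _ = wilson_factorize(stack, tol=1e-12, max_iter=500)
        H_true, _ = synth.var_spectral_matrix(
            var_pair.var_coefficients, var_pair.noise_cov, stack.freqs, FS)
        np.testing.assert_allclose(sigma, var_pair.noise_cov, atol=0.01)
        np.testing.assert_allclose(np.abs(H), np.abs(H_true), rtol=0.01,
                                   atol=1e-3)

    def test_rank_deficient_csd_no_silent_nan(self, rng):
        n = int(2.0 * FS)
        s = rng.normal(size=n)
        trials = [synth.TrialSeries(np.vstack([s, s]), FS,
                                    np.arange(n) / FS)]
        stack = compute_csd(trials, window=(0.4, 2.0))
        try:
            H, sigma, info = wilson_factorize(stack)
            assert np.all(np.isfinite(sigma))
            assert info["diag_load"] > 0
        except RuntimeError as err:
            assert "converge" in str(err)


class TestGrangerSpectrum:
    def test_uncoupled_gc_below_001(self):
        truth = synth.CoupledSourceTruth.gamma_oscillator(coupling=0.0)
        stack = _analytic_stack(truth)
        H, sigma, _ = wilson_factorize(stack, tol=1e-12, max_iter=500)
        fwd, bwd = granger_spectrum(H, sigma, stack.freqs)
        assert np.all(fwd.gc < 0.01)
        assert np.all(bwd.gc < 0.01)

    def test_nonparametric_matches_parametric_5pct(self, var_pair):
        stack = _analytic_stack(var_pair)
        H, sigma, _ = wilson_factorize(stack, tol=1e-12, max_iter=500)
        fwd, bwd = granger_spectrum(H, sigma, stack.freqs)
        gc_p, _ = synth.parametric_gc(var_pair, stack.freqs, FS)
        sel = (stack.freqs >= GAMMA[0]) & (stack.freqs <= GAMMA[1])
        assert abs(fwd.gc[sel].mean() / gc_p[sel].mean() - 1) < 0.05

    def test_geweke_decomposition_identity(self, var_pair):
        """Directed terms plus the instantaneous term reconstruct the total
        interdependence ln(Sxx Syy / det S) within 1e-6."""
        truth = synth.CoupledSourceTruth(
            var_pair.var_coefficients, np.array([[1.0, 0.3], [0.3, 1.0]]))
        freqs = np.arange(1.0, 601.0)
        H, S = synth.var_spectral_matrix(truth.var_coefficients,
                                         truth.noise_cov, freqs, FS)
        g12 = conn._gc_directional(H, truth.noise_cov, 0, 1)
        g21 = conn._gc_directional(H, truth.noise_cov, 1, 0)
        inst = conn.instantaneous_gc(H, truth.noise_cov)
        total = np.log(S[:, 0, 0].real * S[:, 1, 1].real
                       / np.linalg.det(S).real)
        np.testing.assert_allclose(g12 + g21 + inst, total, atol=1e-6)

    def test_channel_swap_symmetry(self, var_pair):
        """Permuting the channel order of the CSD swaps the directed
        spectra exactly (the normalized factorization is unique)."""
        stack = _analytic_stack(var_pair)
        perm = conn.CSDStack(freqs=stack.freqs,
                             csd=stack.csd[:, ::-1, :][:, :, ::-1],
                             n_windows=1, fs=FS)
        H1, s1, _ = wilson_factorize(stack, tol=1e-12, max_iter=500)
        H2, s2, _ = wilson_factorize(perm, tol=1e-12, max_iter=500)
        np.testing.assert_allclose(conn._gc_directional(H1, s1, 0, 1),
                                   conn._gc_directional(H2, s2, 1, 0),
                                   atol=1e-8)
        np.testing.assert_allclose(conn._gc_directional(H1, s1, 1, 0),
                                   conn._gc_directional(H2, s2, 0, 1),
                                   atol=1e-8)

    def test_gc_nonnegative(self, var_pair, rng):
        trials = synth.generate_coupled_pair(var_pair, 10, rng=rng)
        fwd, bwd, _ = gc_from_trials(trials)
        assert np.all(fwd.gc >= 0) and np.all(bwd.gc >= 0)


class TestPooling:
    def test_identity_and_permutation_invariance(self, rng):
        spectra = [rng.random(50) for _ in range(5)]
        assert np.allclose(pool_and_average([spectra[0]]), spectra[0])
        a = pool_and_average(spectra)
        b = pool_and_average(spectra[::-1])
        np.testing.assert_allclose(a, b)

    def test_matches_loop_oracle(self, rng):
        spectra = [rng.random(8) for _ in range(4)]
        out = pool_and_average(spectra)
        expected = np.zeros(8)
        for s in spectra:
            expected += s
        expected /= 4
        np.testing.assert_allclose(out, expected)


class TestClusterTest:
    def test_injected_band_offset_detected(self, rng):
        n_sub, n_freq = 12, 120
        early = rng.normal(0, 1, (n_sub, n_freq))
        late = early + rng.normal(0, 0.3, (n_sub, n_freq))
        late[:, 50:71] += 2.0
        clusters, sig = cluster_test_freq(early, late, n_perm=500, seed=1)
        assert sig[55:66].all()
        assert not sig[:40].any() and not sig[90:].any()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            cluster_test_freq(np.zeros((1, 10)), np.ones((1, 10)))

    def test_identical_conditions_no_clusters(self, rng):
        x = rng.normal(0, 1, (10, 60))
        clusters, sig = cluster_test_freq(x, x + rng.normal(0, 1, x.shape),
                                          n_perm=300, seed=2)
        # may contain chance clusters but none should be extreme
        assert not sig.sum() > 30


class TestTmaxPairs:
    def test_single_pair_reduces_to_simple_permutation(self, rng):
        d = rng.normal(0.5, 1.0, (10, 1))
        res = tmax_pairs_test(d, n_perm=2000, seed=3)
        from repdyn.permutation import permutation_test_1samp
        ref = permutation_test_1samp(d[:, 0], n_perm=2000, seed=3)
        assert res.p[0] == pytest.approx(ref.p[0], abs=1e-12)

    def test_strong_single_pair_effect_isolated(self, rng):
        d = rng.normal(0, 1, (14, 6))
        d[:, 2] += 3.0
        res = tmax_pairs_test(d, n_perm=1000, seed=4)
        assert res.p[2] < 0.05
        assert (res.p[[0, 1, 3, 4, 5]] > 0.05).all()


class TestTimeReversal:
    def test_time_reverse_involution(self, rng):
        ts = synth.TrialSeries(rng.normal(size=(2, 100)), FS,
                               np.arange(100) / FS)
        np.testing.assert_array_equal(time_reverse(time_reverse(ts)).data,
                                      ts.data)

    def test_unidirectional_var_flips_under_reversal(self, rng):
        """The dominant GC direction of a unidirectionally coupled VAR
        flips when the samples are time-reversed."""
        truth = synth.CoupledSourceTruth.gamma_oscillator(coupling=0.15)
        trials = synth.generate_coupled_pair(truth, 30, rng=rng)
        fwd, bwd, _ = gc_from_trials(trials)
        rev = [time_reverse(t) for t in trials]
        fwd_r, bwd_r, _ = gc_from_trials(rev)
        sel = (fwd.freqs >= GAMMA[0]) & (fwd.freqs <= GAMMA[1])
        assert fwd.gc[sel].mean() > bwd.gc[sel].mean()
        assert bwd_r.gc[sel].mean() > fwd_r.gc[sel].mean()

    def test_validated_requires_both_runs(self, rng):
        """A genuine early->late coupling increase is validated; pure white
        noise validates nothing."""
        subject_trials = {}
        for s in range(6):
            t_e = synth.generate_coupled_pair(
                synth.CoupledSourceTruth.gamma_oscillator(coupling=0.05),
                8, rng=rng)
            t_l = synth.generate_coupled_pair(
                synth.CoupledSourceTruth.gamma_oscillator(coupling=0.18),
                8, rng=rng)
            subject_trials[s] = {"early": t_e, "late": t_l}
        res = time_reversal_control(subject_trials, band=GAMMA,
                                    pairs=[("V1", "V4"), ("V4", "V1")],
                                    n_perm=500, seed=5)
        assert res.validated[0]           # forward pair increase validated
        assert res.delta_gc[0] > 0
        assert not np.any(res.validated & ~res.sig_forward)

        noise = {}
        for s in range(6):
            def _wn():
                return [synth.TrialSeries(rng.normal(size=(2, int(2 * FS))),
                                          FS, np.arange(int(2 * FS)) / FS)
                        for _ in range(6)]
            noise[s] = {"early": _wn(), "late": _wn()}
        res_n = time_reversal_control(noise, band=GAMMA,
                                      pairs=[("V1", "V4"), ("V4", "V1")],
                                      n_perm=500, seed=6)
        assert not res_n.validated.any()


class TestPowerRegression:
    def test_power_driven_changes_regress_to_zero(self, rng):
        dp1 = rng.normal(size=40)
        dp2 = rng.normal(size=40)
        delta_gc = 0.7 * dp1 - 0.2 * dp2   # purely power-driven
        out = regress_out_power(delta_gc, dp1, dp2, n_boot=300, seed=1)
        assert abs(out["residual_mean"]) < 1e-10

    def test_true_offset_recovered(self, rng):
        dp1 = rng.normal(size=40)
        dp2 = rng.normal(size=40)
        delta_gc = 0.5 * dp1 + 0.1 * dp2 + 0.02
        out = regress_out_power(delta_gc, dp1, dp2, n_boot=300, seed=2)
        assert out["residual_mean"] == pytest.approx(0.02, abs=1e-10)
        assert out["ci95"][0] <= 0.02 <= out["ci95"][1]


class TestFFFBContrast:
    def test_ff_only_increase_significant(self, rng):
        n_sub, n_pairs = 12, 6
        directions = ["feedforward"] * 3 + ["feedback"] * 3
        delta = rng.normal(0, 0.01, (n_sub, n_pairs))
        delta[:, :3] += 0.05
        validated = np.ones(n_pairs, dtype=bool)
        out = ff_fb_contrast(delta, validated, directions, n_perm=1000,
                             seed=7)
        assert out["p"] < 0.01
        assert out["ff_mean"] > out["fb_mean"]

    def test_subject_without_validated_pairs_excluded(self, rng):
        delta = rng.normal(0, 1, (4, 4))
        validated = np.ones((4, 4), dtype=bool)
        validated[2] = False
        out = ff_fb_contrast(delta, validated,
                             ["feedforward", "feedforward", "feedback",
                              "feedback"], n_perm=200, seed=8)
        assert out["excluded"] == [2]
        assert out["n_subjects_used"] == 3


class TestHierarchy:
    def test_direction_classification(self):
        h = load_hierarchy()
        assert direction_of("V1", "V4", h) == "feedforward"
        assert direction_of("V4", "V1", h) == "feedback"
        assert direction_of("MT", "V6", h) == "lateral"
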
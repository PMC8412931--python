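"""Stage orchestration: simulate -> trajectory -> lmm -> slopes -> gc ->
eyes -> report, driven by one configuration mapping.

The pipeline operates on the per-trial measure table (the schema written by
the synthetic generator and accepted by read_pertrial_table) and writes a
machine-readable results JSON plus a human-readable coefficient summary
with the dual-significance flags. Deterministic given config + seed.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from . import connectivity, io, lmm, synth, trajectory
from .trajectory import smoothing_width

__all__ = ["default_config", "run_pipeline"]

DEFAULT_RESPONSES = ("gamma_power", "gamma_freq", "pupil_constriction", "rt_ms")


def default_config(seed: int = 0, out_dir: str = "repdyn_out") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "stages": ["simulate", "trajectory", "lmm", "slopes", "gc", "eyes",
                   "report"],
        "experiment": {"n_subjects": 30, "trials_per_block": 120},
        "lmm": {"responses": list(DEFAULT_RESPONSES), "n_boot": 200},
        "gc": {"coupling_early": 0.15, "coupling_late": 0.35,
               "n_trials": 40, "band": (40.0, 70.0)},
        "eyes": {"n_trials": 20, "ms_rate": 1.5},
        "table_path": None,   # set to reuse an existing per-trial table
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: dict | None = None) -> dict:
    """Run the configured stages; returns the results dict and writes
    results.json, summary.txt and the per-trial table under out_dir."""
    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    seed = int(cfg["seed"])
    out = pathlib.Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    results: dict = {"seed": seed}
    rng_root = np.random.SeedSequence(seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["simulate", "lmm", "gc", "eyes"], rng_root.spawn(4))}
    results["stage_seeds"] = seeds

    table = None
    if cfg.get("table_path"):
        table = io.read_pertrial_table(cfg["table_path"])
    elif "simulate" in stages:
        exp_cfg = synth.ExperimentConfig(seed=seeds["simulate"],
                                         **cfg["experiment"])
        table = synth.generate_trial_table(exp_cfg)
        io.write_pertrial_table(table, out / "trials.tsv")
    if table is None and any(s in stages for s in ("trajectory", "lmm", "slopes")):
        raise ValueError("stages need a per-trial table: run 'simulate' "
                         "first or set table_path")

    if "trajectory" in stages:
        reps, series = trajectory.subject_average_trajectory(table, "gamma_power")
        smooth = trajectory.running_average(series, smoothing_width(len(series)))
        bl = trajectory.broken_line_fit(smooth)
        ge = trajectory.exp_linear_fit(series, x=reps.astype(float) - 1)
        _, pseries = trajectory.subject_average_trajectory(
            table, "pupil_constriction", blocks=("B", "C", "D"))
        pe = trajectory.exp_linear_fit(pseries)
        results["trajectory"] = {
            "breakpoint": bl.breakpoint,
            "gamma_tau": ge.tau, "gamma_r2_adj": ge.r2_adj,
            "pupil_tau": pe.tau, "pupil_r2_adj": pe.r2_adj,
        }

    if "lmm" in stages:
        lres = {}
        for i, response in enumerate(cfg["lmm"]["responses"]):
            fit = lmm.fit_lmm(table, response=response,
                              n_boot=int(cfg["lmm"]["n_boot"]),
                              seed=seeds["lmm"] + i)
            lres[response] = {
                "coef": dict(zip(fit.names, fit.beta)),
                "se": dict(zip(fit.names, fit.se)),
                "p_satterthwaite": dict(zip(fit.names, fit.satterthwaite_p)),
                "ci95": {n: list(ci) for n, ci in zip(fit.names, fit.boot_ci95)},
                "dual_significant": dict(zip(fit.names,
                                             fit.dual_significant)),
                "var_subject": fit.var_subject,
                "var_orientation": fit.var_orientation,
                "var_residual": fit.var_residual,
            }
        results["lmm"] = lres

    if "slopes" in stages:
        g = lmm.per_subject_slopes(table, "gamma_power")
        p = lmm.per_subject_slopes(table, "pupil_constriction")
        rho_e, p_e = lmm.correlate_slopes(
            g[g.split == "early"].set_index("subject")["slope"],
            p[p.split == "early"].set_index("subject")["slope"])
        rho_l, p_l = lmm.correlate_slopes(
            g[g.split == "late"].set_index("subject")["slope"],
            p[p.split == "late"].set_index("subject")["slope"])
        results["slopes"] = {"gamma_pupil_early_rho": rho_e,
                             "gamma_pupil_early_p": p_e,
                             "gamma_pupil_late_rho": rho_l,
                             "gamma_pupil_late_p": p_l}

    if "gc" in stages:
        gcc = cfg["gc"]
        band = tuple(gcc["band"])
        rng = np.random.default_rng(seeds["gc"])
        rows = {}
        for name, gain in (("early", gcc["coupling_early"]),
                           ("late", gcc["coupling_late"])):
            truth = synth.CoupledSourceTruth.gamma_oscillator(coupling=gain)
            trials = synth.generate_coupled_pair(truth, gcc["n_trials"],
                                                 rng=rng)
            fwd, bwd, info = connectivity.gc_from_trials(
                trials, window=(0.4, 2.0), pair=("V1", "V4"))
            sel = (fwd.freqs >= band[0]) & (fwd.freqs <= band[1])
            pgc_f, pgc_b = synth.parametric_gc(truth, fwd.freqs, 1200.0)
            rows[name] = {
                "gc_forward_band": float(fwd.gc[sel].mean()),
                "gc_backward_band": float(bwd.gc[sel].mean()),
                "parametric_forward_band": float(pgc_f[sel].mean()),
                "factorization_residual": info["residual"],
            }
        results["gc"] = rows

    if "eyes" in stages:
        ec = cfg["eyes"]
        rng = np.random.default_rng(seeds["eyes"])
        from .eyes import detect_microsaccades
        n_true = n_det = 0
        for _ in range(int(ec["n_trials"])):
            _, xy, events = synth.generate_gaze_trace(
                ms_rate=float(ec["ms_rate"]), rng=rng)
            det, _ = detect_microsaccades(xy[:, 0], xy[:, 1], 1000.0)
            n_true += len(events)
            n_det += len(det)
        results["eyes"] = {"injected_events": n_true,
                           "detected_events": n_det}

    if "report" in stages:
        payload = _jsonable(results)
        (out / "results.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))
        lines = ["repdyn pipeline summary", f"seed = {seed}", ""]
        for resp, r in results.get("lmm", {}).items():
            lines.append(f"[{resp}]")
            for name in r["coef"]:
                flag = "*" if r["dual_significant"][name] else " "
                lines.append(
                    f"  {name:20s} {r['coef'][name]: .4g} "
                    f"(p={r['p_satterthwaite'][name]:.3g}, "
                    f"CI=[{r['ci95'][name][0]:.4g}, {r['ci95'][name][1]:.4g}])"
                    f" {flag}")
            lines.append("")
        (out / "summary.txt").write_text("\n".join(lines))
    return results
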
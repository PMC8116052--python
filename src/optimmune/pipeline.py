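"""Stage runners: execute an analysis stage and write CSV/JSON results.

Each runner takes a RunConfig, derives named random substreams from the
root seed, runs the corresponding library routine and writes plain CSV
tables plus a JSON summary (with the config hash and seed) into the
output directory.  The numbered scripts under analysis/ and the CLI are
thin wrappers over these functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_hash, save_config, spawn_rngs
from .decision import KineticParameters, deliberation_time
from .mixture import (
    MixtureEnsemble, dominant_modes, histogram_modes, optimize_mixture,
    usage_probability,
)
from .optimize import divergence_scan, lifetime_scan, optimize_strategy

__all__ = [
    "run_optimize", "run_phase_diagram", "run_mixture",
    "run_lifetime_scan", "run_demo",
]

SCHEMA_VERSION = 1


def _write_summary(outdir: Path, name: str, cfg: RunConfig, payload: dict) -> dict:
    summary = {
        "schema_version": SCHEMA_VERSION,
        "stage": name,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
        **payload,
    }
    (outdir / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _prepare(cfg: RunConfig, name: str) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / f"{name}_config.yaml")
    return outdir


def run_optimize(cfg: RunConfig) -> dict:
    """Grid-optimize (alpha, beta) at one antigenic divergence."""
    outdir = _prepare(cfg, "optimize")
    rngs = spawn_rngs(cfg.seed, "optimize")
    res = optimize_strategy(
        cfg.kernel(), cfg.process(), cfg.cost(), cfg.grid, cfg.L,
        cfg.n_ensembles, rngs["optimize"], cfg.beta_max, cfg.memory_update)
    res.surface.to_csv(outdir / "optimize_surface.csv", index=False)
    return _write_summary(outdir, "optimize", cfg, {
        "delta_hat": cfg.delta_hat,
        "alpha_hat_star": res.alpha_hat_star,
        "beta_hat_star": res.beta_hat_star,
        "u_net_star": res.u_net_star,
        "usage_fraction": res.usage_star,
        "k_max": res.k_max,
    })


def run_phase_diagram(cfg: RunConfig) -> dict:
    """Divergence scan of optimal strategies (the phase diagram)."""
    outdir = _prepare(cfg, "phase_diagram")
    df = divergence_scan(
        cfg.kernel(), cfg.cost(), list(cfg.scan_delta_hats), cfg.grid,
        cfg.L, cfg.scan_n_ensembles, cfg.seed, cfg.beta_max, cfg.rel_sd,
        cfg.drift_scaling, cfg.memory_update)
    df.to_csv(outdir / "phase_diagram_scan.csv", index=False)
    below = df[df["alpha_hat_star"] < 0.95]
    first_drop = float(below["delta_hat"].iloc[0]) if len(below) else float("nan")
    at_bound = df[df["alpha_hat_star"] >= 0.95]
    last_specific = float(at_bound["delta_hat"].iloc[-1]) if len(at_bound) else 0.0
    return _write_summary(outdir, "phase_diagram", cfg, {
        "delta_hats": list(map(float, cfg.scan_delta_hats)),
        "first_delta_hat_below_095": first_drop,
        "last_delta_hat_at_bound": last_specific,
    })


def run_mixture(cfg: RunConfig) -> dict:
    """Repeated mixture optimizations, pooled histogram and usage curve."""
    outdir = _prepare(cfg, "mixture")
    rngs = spawn_rngs(cfg.seed, "init", "ascent", "usage")
    beta = cfg.beta_hat_tilde * cfg.beta_max / cfg.n_m
    vectors = []
    for r in range(cfg.n_restarts):
        init = rngs["init"].uniform(0.0, cfg.alpha_max, size=cfg.n_m)
        vec = optimize_mixture(
            init, cfg.kernel(), beta, cfg.delta_hat_range,
            n_steps=cfg.n_steps, n_probe=cfg.n_probe,
            n_antigens=cfg.n_antigens, L=cfg.mixture_L,
            rng=rngs["ascent"], rel_sd=cfg.rel_sd,
            drift_scaling=cfg.drift_scaling, beta_max=cfg.beta_max)
        vectors.append(vec)
    ensemble = MixtureEnsemble(vectors, cfg.alpha_max, cfg.bin_width)
    centers, dens = ensemble.histogram()
    modes = histogram_modes(centers, dens)
    two_modes = dominant_modes(centers, dens, k=2)
    usage = usage_probability(
        ensemble, cfg.kernel(), beta, cfg.delta_hat_range, cfg.n_test,
        cfg.mixture_L, rngs["usage"], cfg.rel_sd, cfg.drift_scaling)
    import pandas as pd
    pd.DataFrame(
        np.vstack(vectors),
        columns=[f"alpha_{i}" for i in range(cfg.n_m)],
    ).to_csv(outdir / "mixture_restarts.csv", index=False)
    pd.DataFrame({"alpha_hat_bin": centers, "density": dens}).to_csv(
        outdir / "mixture_histogram.csv", index=False)
    usage.to_csv(outdir / "mixture_usage.csv", index=False)
    return _write_summary(outdir, "mixture", cfg, {
        "beta_hat_tilde": cfg.beta_hat_tilde,
        "modes": modes,
        "low_mode": two_modes[0] if two_modes else float("nan"),
        "high_mode": two_modes[-1] if two_modes else float("nan"),
    })


def run_lifetime_scan(cfg: RunConfig) -> dict:
    """Optimal strategies versus life expectancy."""
    outdir = _prepare(cfg, "lifetime_scan")
    df, c_star = lifetime_scan(
        cfg.kernel(), cfg.process(), cfg.cost(), list(cfg.L_list),
        cfg.grid, cfg.n_ensembles, cfg.seed, cfg.beta_max,
        cfg.memory_update)
    df.to_csv(outdir / "lifetime_scan.csv", index=False)
    first = df.iloc[0]
    return _write_summary(outdir, "lifetime_scan", cfg, {
        "delta_hat": cfg.delta_hat,
        "c_star": c_star,
        "shortest_L": int(first["L"]),
        "alpha_hat_star_shortest": float(first["alpha_hat_star"]),
        "beta_hat_star_shortest": float(first["beta_hat_star"]),
    })


def run_demo(cfg: RunConfig) -> dict:
    """End-to-end smoke run producing every output type on tiny budgets."""
    outdir = _prepare(cfg, "demo")
    kp = KineticParameters(tau0=1.0, t_half=0.5, b=2.0)
    results = {
        "deliberation_time_days": deliberation_time(kp),
        "optimize": run_optimize(cfg),
        "phase_diagram": run_phase_diagram(cfg),
        "mixture": run_mixture(cfg),
        "lifetime_scan": run_lifetime_scan(cfg),
    }
    return _write_summary(outdir, "demo", cfg, {
        "deliberation_time_days": results["deliberation_time_days"],
        "stages": ["optimize", "phase_diagram", "mixture", "lifetime_scan"],
    })
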
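"""Run configuration, presets, deterministic seeding and serialization."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RunConfig", "load_config", "save_config", "config_hash", "preset",
    "spawn_rngs",
]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of a pipeline run."""

    # kernel
    alpha_max: float = 4.0
    theta: float = 2.0
    e_max: float = 1.0
    # deliberation
    beta_max: float = 10.0
    cost_form: str = "linear"
    omega0_hat: float = 0.1
    # pathogen drift
    delta_hat: float = 0.2
    delta_hat_range: tuple[float, float] = (0.0, 1.6)
    rel_sd: float = 0.05
    drift_scaling: str = "sqrt"
    memory_update: str = "anchored"
    # budgets
    grid: tuple[int, int] = (50, 50)
    L: int = 60
    n_ensembles: int = 200
    scan_delta_hats: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.601, 0.05), 3))
    scan_n_ensembles: int = 120
    L_list: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 24, 32, 40, 50, 60)
    # mixture budgets
    n_m: int = 20
    beta_hat_tilde: float = 0.2
    n_restarts: int = 24
    n_steps: int = 2000
    n_probe: int = 30
    n_antigens: int = 50
    mixture_L: int = 40
    n_test: int = 500
    bin_width: float = 0.05
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> "RunConfig":
        from .decision import DeliberationCost
        from .pathogen import PathogenProcess

        DeliberationCost(self.cost_form, self.omega0_hat)
        PathogenProcess(self.delta_hat / self.alpha_max, self.rel_sd,
                        self.drift_scaling)
        if self.memory_update not in ("anchored", "reset"):
            raise ValueError("memory_update must be 'anchored' or 'reset'")
        if self.alpha_max <= 0 or self.beta_max <= 0 or self.e_max <= 0:
            raise ValueError("scale parameters must be positive")
        return self

    def kernel(self):
        from .kernels import AffinityKernel
        return AffinityKernel(self.alpha_max, self.theta, self.alpha_max,
                              self.e_max)

    def cost(self):
        from .decision import DeliberationCost
        return DeliberationCost(self.cost_form, self.omega0_hat)

    def process(self, delta_hat: float | None = None):
        from .pathogen import PathogenProcess
        dh = self.delta_hat if delta_hat is None else delta_hat
        return PathogenProcess(dh / self.alpha_max, self.rel_sd,
                               self.drift_scaling)


def _to_plain(obj):
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {k: _to_plain(v) for k, v in asdict(cfg).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path: str | Path, **overrides) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    # restore tuple-typed fields
    for key in ("delta_hat_range", "grid", "scan_delta_hats", "L_list"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data).validate()


def config_hash(cfg: RunConfig) -> str:
    data = {k: _to_plain(v) for k, v in asdict(cfg).items()}
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def spawn_rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Named independent random streams derived from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_PRESETS = {
    # single-strategy phase diagram (Gaussian kernel, linear cost)
    "fig2": dict(delta_hat=0.2, cost_form="linear", omega0_hat=0.1,
                 theta=2.0, alpha_max=4.0, beta_max=10.0),
    # mixture bimodality at fixed effective deliberation
    "fig3": dict(cost_form="none", beta_hat_tilde=0.2,
                 delta_hat_range=(0.0, 1.6), n_m=20),
    # life-expectancy scans at moderate divergence
    "fig4a": dict(delta_hat=0.35, cost_form="linear", omega0_hat=0.1),
    "fig4b": dict(delta_hat=0.5, cost_form="linear", omega0_hat=0.1),
    # tiny smoke-test budgets
    "demo": dict(delta_hat=0.3, grid=(12, 12), L=10, n_ensembles=20,
                 scan_delta_hats=(0.1, 0.4), scan_n_ensembles=10,
                 L_list=(2, 6, 10), n_restarts=2, n_steps=10, n_probe=25,
                 n_antigens=8, mixture_L=8, n_test=40),
}


def preset(name: str, **overrides) -> RunConfig:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choices: {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return RunConfig(**params).validate()
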
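"""Grid-search optimization of single-memory strategies.

The optimal strategy maximizes the total net utility accumulated over
a lifetime of encounters,

    (alpha*, beta*) = argmax_{alpha, beta}  sum_i U_net(t_i),

estimated on a uniform (alpha_hat, beta_hat) grid with common random
numbers: every grid cell faces the same antigenic trajectories, so the
argmax location is far less noisy than independent sampling would
allow at desk-scale ensemble counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import batch_lifetime_sweep
from ._tables import get_table
from .decision import DeliberationCost
from .kernels import AffinityKernel
from .pathogen import PathogenProcess

__all__ = [
    "OptimizationResult",
    "optimize_strategy",
    "divergence_scan",
    "lifetime_scan",
    "phase_surface",
]


@dataclass
class OptimizationResult:
    """Argmax strategy plus the full utility surface."""

    alpha_star: float
    beta_star: float
    alpha_hat_star: float
    beta_hat_star: float
    u_net_star: float          # per-encounter net utility at the argmax
    usage_star: float
    k_max: float               # max mean dissipation over the surface
    surface: pd.DataFrame = field(repr=False)
    delta_hat: float = 0.0
    L: int = 0


def _draw_shared(rng: np.random.Generator, n_ensembles: int, L: int):
    z = rng.standard_normal((n_ensembles, L))
    u = rng.uniform(size=(n_ensembles, L))
    return z, u


def optimize_strategy(
    kernel_family: AffinityKernel,
    process: PathogenProcess,
    cost: DeliberationCost,
    grid: tuple[int, int] = (50, 50),
    L: int = 60,
    n_ensembles: int = 200,
    rng: np.random.Generator | None = None,
    beta_max: float = 10.0,
    memory_update: str = "anchored",
) -> OptimizationResult:
    """Exhaustive grid search over scaled (alpha_hat, beta_hat).

    The objective per cell is the ensemble mean of the total lifetime
    net utility (all encounters, primary included).  Ties are broken
    toward the cheaper strategy: smallest beta, then smallest alpha.
    """
    n_alpha, n_beta = grid
    if n_alpha < 2 or n_beta < 2:
        raise ValueError("grid must be at least 2x2")
    if L < 2:
        raise ValueError("L must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    alpha_max = kernel_family.alpha_max
    theta = kernel_family.theta
    e_max = kernel_family.e_max
    ah = np.linspace(0.0, 1.0, n_alpha)
    bh = np.linspace(0.0, 1.0, n_beta)
    AH, BH = np.meshgrid(ah, bh, indexing="ij")
    alphas = np.ascontiguousarray((AH * alpha_max).ravel())
    betas = np.ascontiguousarray((BH * beta_max).ravel())
    omega_hats = np.ascontiguousarray(cost.omega_hat(betas / beta_max))
    z, u = _draw_shared(rng, n_ensembles, L)
    table = get_table(theta)
    n_cells = alphas.size
    tot = np.empty(n_cells)
    scored = np.empty(n_cells)
    usage = np.empty(n_cells)
    kmean = np.empty(n_cells)
    batch_lifetime_sweep(
        alphas, betas, omega_hats, alpha_max, e_max, theta,
        process.delta, process.rel_sd,
        process.drift_scaling == "sqrt", memory_update == "anchored",
        L, z, u, *table.args, tot, scored, usage, kmean,
    )
    # argmax with cheap-strategy tie-breaking (min beta, then min alpha)
    best = tot.max()
    ties = np.flatnonzero(tot >= best - 1e-15)
    order = np.lexsort((alphas[ties], betas[ties]))
    j = int(ties[order[0]])
    surface = pd.DataFrame({
        "alpha_hat": AH.ravel(), "beta_hat": BH.ravel(),
        "u_net_total": tot, "u_net_per_encounter": tot / L,
        "u_net_scored": scored, "usage_fraction": usage,
        "k_diss_mean": kmean,
    })
    return OptimizationResult(
        alpha_star=float(alphas[j]), beta_star=float(betas[j]),
        alpha_hat_star=float(AH.ravel()[j]), beta_hat_star=float(BH.ravel()[j]),
        u_net_star=float(tot[j] / L), usage_star=float(usage[j]),
        k_max=float(kmean.max()), surface=surface,
        delta_hat=process.delta_hat(alpha_max), L=L,
    )


def divergence_scan(
    kernel_family: AffinityKernel,
    cost: DeliberationCost,
    delta_hat_list,
    grid: tuple[int, int] = (50, 50),
    L: int = 60,
    n_ensembles: int = 200,
    seed: int = 0,
    beta_max: float = 10.0,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
    memory_update: str = "anchored",
) -> pd.DataFrame:
    """Optimal strategy as a function of antigenic divergence.

    Each divergence value is optimized with an identical random stream
    (fresh generator from the same seed), so the scan is a controlled
    comparison across delta_hat.
    """
    rows = []
    for dh in delta_hat_list:
        process = PathogenProcess(
            dh / kernel_family.alpha_max, rel_sd, drift_scaling)
        res = optimize_strategy(
            kernel_family, process, cost, grid, L, n_ensembles,
            np.random.default_rng(seed), beta_max, memory_update)
        rows.append((dh, res.alpha_hat_star, res.beta_hat_star,
                     res.u_net_star, res.usage_star, res.k_max))
    return pd.DataFrame(
        rows, columns=["delta_hat", "alpha_hat_star", "beta_hat_star",
                       "u_net_star", "usage_fraction", "k_max"])


def phase_surface(
    kernel_family: AffinityKernel,
    cost: DeliberationCost,
    delta_hat_list,
    grid: tuple[int, int] = (50, 50),
    L: int = 60,
    n_ensembles: int = 120,
    seed: int = 0,
    beta_max: float = 10.0,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
    memory_update: str = "anchored",
    k_frac: float = 0.4,
    usage_cut: float = 0.5,
) -> pd.DataFrame:
    """Net utility and dissipation over the (delta_hat, beta_hat) plane.

    For each divergence the specificity is fixed at its optimum and the
    beta_hat axis of that optimization's surface is extracted.  Cells
    are labelled by response regime: dissipation above ``k_frac`` of
    the surface maximum marks *non-equilibrium memory*; below it,
    cells split into *equilibrium memory* (memory answers at least
    ``usage_cut`` of encounters) and *equilibrium naive*.
    """
    frames = []
    for dh in delta_hat_list:
        process = PathogenProcess(
            dh / kernel_family.alpha_max, rel_sd, drift_scaling)
        res = optimize_strategy(
            kernel_family, process, cost, grid, L, n_ensembles,
            np.random.default_rng(seed), beta_max, memory_update)
        sub = res.surface[
            res.surface["alpha_hat"] == res.alpha_hat_star].copy()
        sub.insert(0, "delta_hat", dh)
        sub["alpha_hat_star"] = res.alpha_hat_star
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)
    k_max = df["k_diss_mean"].max()
    df["k_rel"] = df["k_diss_mean"] / k_max if k_max > 0 else 0.0
    dissipative = df["k_rel"] >= k_frac
    used = df["usage_fraction"] >= usage_cut
    df["regime"] = np.where(
        dissipative, "non-equilibrium memory",
        np.where(used, "equilibrium memory", "equilibrium naive"))
    return df


def lifetime_scan(
    kernel_family: AffinityKernel,
    process: PathogenProcess,
    cost: DeliberationCost,
    L_list,
    grid: tuple[int, int] = (50, 50),
    n_ensembles: int = 200,
    seed: int = 0,
    beta_max: float = 10.0,
    memory_update: str = "anchored",
    ensemble_budget: int | None = 12000,
    max_ensembles: int = 4000,
) -> tuple[pd.DataFrame, int]:
    """Optimal strategy as a function of life expectancy L.

    Short lifetimes average over fewer encounters, so the per-L
    ensemble count is scaled to keep the total number of simulated
    encounters roughly constant (``ensemble_budget``), bounded by
    ``max_ensembles``.  Returns the scan table and the transition point
    c*: the life expectancy at which the optimal specificity attains
    its minimum (specificity rises again for longer-lived hosts).
    """
    rows = []
    for L in L_list:
        if ensemble_budget is None:
            n_ens = n_ensembles
        else:
            n_ens = int(np.clip(ensemble_budget // max(L, 1),
                                n_ensembles, max_ensembles))
        res = optimize_strategy(
            kernel_family, process, cost, grid, int(L), n_ens,
            np.random.default_rng(seed), beta_max, memory_update)
        rows.append((int(L), res.alpha_hat_star, res.beta_hat_star,
                     res.u_net_star, res.usage_star))
    df = pd.DataFrame(
        rows, columns=["L", "alpha_hat_star", "beta_hat_star",
                       "u_net_star", "usage_fraction"])
    c_star = int(df.loc[df["alpha_hat_star"].idxmin(), "L"])
    return df, c_star
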
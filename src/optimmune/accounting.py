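"""Per-encounter accounting: expected profile, dissipation, net utility.

Against an antigen at distance ``d`` from the stored memory, the
mounted response is memory with probability ``p_mem`` and naive with
probability ``p_naive``.  The expected binding profile is the
probability-weighted mixture of the memory-centered profile and the
freshly-centered (naive) profile; its KL divergence from the fresh
profile, in units of the deliberation factor, is the dissipation
``K_diss`` -- the price of deciding on the fly instead of always
mounting the energetically optimal response.  The net utility of the
encounter is ``U_net = <U> - K_diss``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tables import DissipationTable, get_table
from .decision import DeliberationCost, recognition_probabilities
from .kernels import AffinityKernel, ProfileGrid, binding_affinity, default_grid_spec, normalized_profile

__all__ = [
    "EncounterOutcome",
    "expected_profile",
    "dissipation",
    "net_utility",
]


@dataclass
class EncounterOutcome:
    """Deterministic bookkeeping for one infection round.

    ``memory_used`` is left unset here; the lifetime simulator fills it
    with the realized Bernoulli(p_mem) draw.
    """

    d: float
    p_mem: float
    p_naive: float
    u_mem: float
    u_naive: float
    expected_utility: float
    k_diss: float
    u_net: float
    memory_used: bool | None = None

    def __post_init__(self) -> None:
        if self.k_diss < -1e-12:
            raise ValueError("dissipation must be nonnegative")


def expected_profile(
    kernel: AffinityKernel,
    memory_center: float,
    antigen_center: float,
    beta: float,
    grid_spec: tuple[float, float, int] | None = None,
) -> ProfileGrid:
    """Decision-weighted mixture of memory and fresh profiles.

    Weights are (p_mem, p_naive) evaluated at the memory-antigen
    distance; the result is itself normalized since it mixes normalized
    profiles with weights summing to one.
    """
    if grid_spec is None:
        grid_spec = default_grid_spec(kernel, [memory_center, antigen_center])
    d = abs(memory_center - antigen_center)
    p_mem, p_naive = recognition_probabilities(kernel, d, beta)
    mem_prof = normalized_profile(kernel, memory_center, grid_spec)
    new_prof = normalized_profile(kernel, antigen_center, grid_spec)
    return ProfileGrid(
        mem_prof.positions, p_mem * mem_prof.weights + p_naive * new_prof.weights
    )


def dissipation(
    kernel: AffinityKernel,
    d: float,
    beta: float,
    grid_spec: tuple[float, float, int] | None = None,
) -> float:
    """K_diss by direct profile construction (the reference path).

    Computes (1/beta) * KL(expected || fresh) on an explicit grid.  The
    ``beta = 0`` limit is 0 by continuity (no memory engagement, so the
    expected profile equals the fresh one); so are ``alpha = 0`` and
    ``theta = 0``, where the two profiles coincide or are undefined in
    a way that carries no decision weight.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if beta == 0.0 or kernel.alpha == 0.0 or kernel.theta == 0.0 or d == 0.0:
        return 0.0
    if grid_spec is None:
        grid_spec = default_grid_spec(kernel, [0.0, d])
    mix = expected_profile(kernel, 0.0, d, beta, grid_spec)
    ref = normalized_profile(kernel, d, grid_spec)
    p = mix.weights
    # analytic log of the reference avoids underflow far from its center
    logq_raw = np.zeros_like(ref.positions)
    x = np.abs(ref.positions - d)
    logq_raw = -(kernel.alpha * x) ** kernel.theta
    logz = np.log(np.exp(logq_raw).sum())
    logq = logq_raw - logz
    mask = p > 0
    kl = float(np.sum(p[mask] * (np.log(p[mask]) - logq[mask])))
    return max(kl, 0.0) / beta


def net_utility(
    kernel: AffinityKernel,
    d: float,
    beta: float,
    cost: DeliberationCost,
    beta_max: float = 10.0,
    grid_spec: tuple[float, float, int] | None = None,
    table: DissipationTable | None = None,
) -> EncounterOutcome:
    """Assemble the deterministic outcome of one encounter.

    Dissipation is taken from the precomputed table by default; passing
    ``grid_spec`` forces the direct profile computation instead.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    p_mem, p_naive = recognition_probabilities(kernel, d, beta)
    u_naive = -kernel.e_max * cost.omega_hat(beta / beta_max)
    e = binding_affinity(kernel, d)
    u_mem = u_naive + e
    expected = u_mem * p_mem + u_naive * p_naive
    if grid_spec is not None:
        k = dissipation(kernel, d, beta, grid_spec)
    else:
        if table is None:
            table = get_table(kernel.theta)
        k = table.k_diss(kernel.alpha, d, beta, kernel.e_max, kernel.alpha_max)
    return EncounterOutcome(
        d=d, p_mem=p_mem, p_naive=p_naive, u_mem=u_mem, u_naive=u_naive,
        expected_utility=expected, k_diss=k, u_net=expected - k,
    )
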
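"""Maximum-entropy decision rule between memory and naive responses.

Upon infection, a stored memory receptor either recognizes the antigen
during the deliberation window (a memory response) or the window
elapses and a novel naive response is initiated.  The recognition
probability follows first-order binding kinetics,

    P_naive = exp(-E(d) * beta),    P_mem = 1 - P_naive,

where ``E(d)`` is the memory receptor's affinity to the (possibly
evolved) antigen and ``beta`` -- the deliberation factor -- is the
pathogen load accumulated over the deliberation time tau.  The same
``beta`` plays the role of inverse temperature in the equivalent
maximum-entropy description, Q_a ~ exp(beta * U_a): equating the two
descriptions fixes the utility gap between memory and naive responses,
``beta * (U_mem - U_naive) = log(exp(E * beta) - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernels import AffinityKernel, binding_affinity

__all__ = [
    "Strategy",
    "DeliberationCost",
    "KineticParameters",
    "NEVER_MEMORY",
    "deliberation_time",
    "recognition_probabilities",
    "utilities",
    "decision_distribution",
    "utility_gap_from_recognition",
]

#: sentinel utility gap for E*beta = 0: memory can never be engaged.
NEVER_MEMORY = -math.inf


@dataclass(frozen=True)
class Strategy:
    """A single-memory immune strategy: specificity and deliberation."""

    alpha: float
    beta: float
    beta_max: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= self.beta_max:
            raise ValueError(
                f"beta={self.beta} outside [0, beta_max={self.beta_max}]"
            )

    @property
    def beta_hat(self) -> float:
        return self.beta / self.beta_max


@dataclass(frozen=True)
class DeliberationCost:
    """Cost of pathogen proliferation during deliberation.

    The naive response's negative utility is ``-e_max * omega_hat``
    with ``omega_hat`` one of 0 (none), ``omega0_hat * beta_hat``
    (linear) or ``omega0_hat * beta_hat**2`` (quadratic).
    """

    form: str = "linear"
    omega0_hat: float = 0.1

    def __post_init__(self) -> None:
        if self.form not in ("none", "linear", "quadratic"):
            raise ValueError(f"unknown cost form {self.form!r}")
        if self.omega0_hat < 0:
            raise ValueError("omega0_hat must be >= 0")

    def omega_hat(self, beta_hat) -> np.ndarray | float:
        """Scaled cost Omega/e_max at scaled deliberation beta_hat."""
        b = np.asarray(beta_hat, dtype=float)
        if self.form == "none":
            out = np.zeros_like(b)
        elif self.form == "linear":
            out = self.omega0_hat * b
        else:
            out = self.omega0_hat * b**2
        return out if np.ndim(beta_hat) else float(out)


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic determinants of the deliberation window.

    tau0 is the head start of memory over naive initiation (days),
    t_half the doubling time of recruited cells (days), and b the
    ratio of memory to naive recruitment size.
    """

    tau0: float
    t_half: float
    b: float

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.t_half <= 0 or self.b <= 0:
            raise ValueError("kinetic parameters must be positive")


def deliberation_time(kp: KineticParameters) -> float:
    """Time for a naive clone to catch up with memory, in days.

    tau = tau0 + t_half * ln(b) / ln(2): the memory head start plus the
    doublings needed to offset the b-fold recruitment advantage.
    """
    return kp.tau0 + kp.t_half * math.log(kp.b) / math.log(2.0)


def recognition_probabilities(
    kernel: AffinityKernel, d, beta: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(P_mem, P_naive) for a memory at distance ``d`` from the antigen."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    e = binding_affinity(kernel, d)
    p_naive = np.exp(-np.asarray(e, dtype=float) * beta)
    p_mem = -np.expm1(-np.asarray(e, dtype=float) * beta)
    if np.ndim(d):
        return p_mem, p_naive
    return float(p_mem), float(p_naive)


def utilities(
    kernel: AffinityKernel,
    d,
    beta: float,
    cost: DeliberationCost,
    beta_max: float = 10.0,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(U_mem, U_naive) at distance ``d``.

    The naive response pays the deliberation cost, U_naive =
    -e_max * omega_hat(beta_hat); a memory response adds the binding
    affinity on top, U_mem = U_naive + E(d).
    """
    u_naive = -kernel.e_max * cost.omega_hat(beta / beta_max)
    e = binding_affinity(kernel, d)
    return u_naive + e, (u_naive if np.ndim(d) == 0 else np.full(np.shape(d), u_naive))


def decision_distribution(u_mem: float, u_naive: float, beta: float,
                          prior_mem: float = 0.5) -> float:
    """Max-entropy probability of choosing memory, Q_mem.

    The general prior-weighted rule Q_mem = p * e^(beta*U_mem) /
    (p * e^(beta*U_mem) + (1-p) * e^(beta*U_naive)); with the default
    uniform prior (the immune system has no intrinsic preference) this
    is logistic in beta * (u_mem - u_naive).  Computed via a
    log-sum-exp guard so it stays finite for |beta * dU| up to ~1e3.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not 0.0 <= prior_mem <= 1.0:
        raise ValueError("prior_mem must be a probability")
    if prior_mem == 0.0:
        return 0.0
    if prior_mem == 1.0:
        return 1.0
    x = beta * (u_mem - u_naive) + math.log(prior_mem / (1.0 - prior_mem))
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x) / (1.0 + math.exp(x))


def utility_gap_from_recognition(e: float, beta: float) -> float:
    """Utility gap U_mem - U_naive consistent with the recognition law.

    dU = log(exp(E * beta) - 1) / beta.  At E*beta = ln 2 the gap is
    zero (indifference); for E*beta >> 1 it approaches E.  E*beta = 0
    returns the NEVER_MEMORY sentinel (-inf): memory is never engaged.
    """
    if e * beta < 0:
        raise ValueError("E and beta must be nonnegative")
    x = e * beta
    if x == 0.0:
        return NEVER_MEMORY
    if x > 30.0:
        # log(e^x - 1) = x + log1p(-e^-x)
        return (x + math.log1p(-math.exp(-x))) / beta
    return math.log(math.expm1(x)) / beta
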
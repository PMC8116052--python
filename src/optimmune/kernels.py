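"""Affinity kernels on a one-dimensional antigenic shape space.

Receptor-antigen recognition is modelled by a binding kernel

    E(d) = e_max * (alpha / alpha_max) * exp[-(alpha * d)^theta]

where ``d`` is the antigenic distance between the receptor's cognate
antigen and the target, ``alpha`` is the receptor's specificity (the
inverse of its cross-reactive range) and ``theta`` tunes the profile
shape: flat for theta=0, double-sided exponential for theta=1, Gaussian
for theta=2 and increasingly top-hat-like beyond.  The prefactor
``alpha/alpha_max`` encodes the affinity--cross-reactivity tradeoff:
sharper profiles bind their cognate antigen more strongly, with the peak
affinity reaching ``e_max`` at ``alpha = alpha_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffinityKernel",
    "ProfileGrid",
    "binding_affinity",
    "normalized_profile",
    "default_grid_spec",
]


@dataclass(frozen=True)
class AffinityKernel:
    """Parameters of the affinity-specificity tradeoff kernel.

    Attributes
    ----------
    alpha:
        Specificity, in inverse antigenic-distance units.  ``1/alpha``
        is the cross-reactive range of the receptor.
    theta:
        Shape factor (dimensionless, >= 0).
    alpha_max:
        Upper bound on specificity; sets the scale of the tradeoff.
    e_max:
        Peak affinity (utility units) reached at ``alpha == alpha_max``
        and zero distance.
    """

    alpha: float
    theta: float = 2.0
    alpha_max: float = 4.0
    e_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= self.alpha_max:
            raise ValueError(
                f"alpha={self.alpha} outside [0, alpha_max={self.alpha_max}]"
            )
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if self.e_max <= 0:
            raise ValueError(f"e_max must be > 0, got {self.e_max}")

    @property
    def alpha_hat(self) -> float:
        """Scaled specificity alpha/alpha_max in [0, 1]."""
        return self.alpha / self.alpha_max

    def with_alpha(self, alpha: float) -> "AffinityKernel":
        return AffinityKernel(alpha, self.theta, self.alpha_max, self.e_max)


@dataclass(frozen=True)
class ProfileGrid:
    """A discretized, normalized binding profile on a uniform 1-D grid."""

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if pos.ndim != 1 or pos.shape != w.shape:
            raise ValueError("positions and weights must be matching 1-D arrays")
        dpos = np.diff(pos)
        if np.any(dpos <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(dpos, dpos[0], rtol=1e-9, atol=1e-12):
            raise ValueError("positions must be uniformly spaced")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


def binding_affinity(kernel: AffinityKernel, d) -> np.ndarray | float:
    """Binding affinity of a receptor at antigenic distance ``d``.

    Evaluates ``e_max * (alpha/alpha_max) * exp[-(alpha*d)^theta]``.
    The 0^0 convention is 1, so ``theta = 0`` yields a flat profile of
    height ``e_max * alpha/alpha_max`` (no tradeoff) and ``d = 0`` is
    always the peak.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("antigenic distance must be >= 0")
    if kernel.theta == 0.0:
        out = np.full_like(d_arr, kernel.e_max * kernel.alpha_hat)
    else:
        out = kernel.e_max * kernel.alpha_hat * np.exp(
            -((kernel.alpha * d_arr) ** kernel.theta)
        )
    return out if np.ndim(d) else float(out)


def default_grid_spec(
    kernels: "AffinityKernel | list[AffinityKernel]",
    centers: "float | list[float]" = 0.0,
    span_factor: float = 8.0,
    n_points: int = 801,
) -> tuple[float, float, int]:
    """Grid covering all profile centers plus ``span_factor`` widths.

    The span is measured in units of the widest cross-reactive range
    ``1/alpha`` among the kernels, so that every profile decays to
    numerical zero well inside the grid.
    """
    if isinstance(kernels, AffinityKernel):
        kernels = [kernels]
    cs = np.atleast_1d(np.asarray(centers, dtype=float))
    widths = [1.0 / k.alpha for k in kernels if k.alpha > 0]
    if not widths:
        raise ValueError("at least one kernel must have alpha > 0")
    half = span_factor * max(widths)
    mid = 0.5 * (cs.min() + cs.max())
    reach = 0.5 * (cs.max() - cs.min())
    return (mid - reach - half, mid + reach + half, n_points)


def normalized_profile(
    kernel: AffinityKernel,
    center: float,
    grid_spec: tuple[float, float, int],
) -> ProfileGrid:
    """Discretize the kernel at ``center`` and normalize it to sum 1.

    Raises if the grid does not contain the center or if the profile is
    identically zero (``alpha = 0``), for which a normalized profile is
    undefined.
    """
    lo, hi, n = grid_spec
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    if not lo <= center <= hi:
        raise ValueError(f"grid [{lo}, {hi}] does not cover center {center}")
    positions = np.linspace(lo, hi, int(n))
    if kernel.alpha == 0.0:
        raise ValueError("normalization undefined for alpha = 0 (zero profile)")
    vals = binding_affinity(kernel, np.abs(positions - center))
    total = vals.sum()
    if total <= 0:
        raise ValueError("profile vanishes on the grid; widen the grid")
    return ProfileGrid(positions, vals / total)
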
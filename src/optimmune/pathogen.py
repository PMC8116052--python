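"""Synthetic antigenic-drift generator.

Pathogen evolution is modelled as diffusion in antigenic shape space:
after ``k`` infection rounds the squared antigenic distance from the
reference antigen satisfies ``<d_k^2> = k * delta^2``, where ``delta``
is the antigenic divergence per round.  A round's realized distance is
drawn from a normal law centered on the rms divergence with a small
relative width (default 5%), truncated at zero; the width stands in for
how a single evolutionary trajectory samples the multi-dimensional
shape space around the reference antigen.

Distances are the only synthetic "data" the analyses consume; the
scaled divergence ``delta_hat = delta * alpha_max`` expresses drift per
round in units of the minimal cross-reactive range ``1/alpha_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathogenProcess",
    "sample_antigenic_distance",
    "divergence_grid",
    "trajectory_frame",
]

#: scaling laws for the mean distance after k rounds
_DRIFT_SCALINGS = ("sqrt", "linear")


@dataclass(frozen=True)
class PathogenProcess:
    """Antigenic drift of one evolving pathogen lineage.

    ``drift_scaling`` selects the growth of the expected distance with
    the number of rounds ``k`` since the reference infection: ``sqrt``
    (the diffusive law, mean ``delta * sqrt(k)``; default) or
    ``linear`` (mean ``delta * k``, i.e. ballistic drift).
    """

    delta: float
    rel_sd: float = 0.05
    drift_scaling: str = "sqrt"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")
        if self.drift_scaling not in _DRIFT_SCALINGS:
            raise ValueError(f"drift_scaling must be one of {_DRIFT_SCALINGS}")

    def delta_hat(self, alpha_max: float) -> float:
        """Divergence per round scaled by the minimal cross-reactive range."""
        return self.delta * alpha_max

    def mean_distance(self, k) -> np.ndarray | float:
        """Expected distance after ``k`` rounds of drift."""
        k_arr = np.asarray(k, dtype=float)
        if self.drift_scaling == "sqrt":
            out = self.delta * np.sqrt(k_arr)
        else:
            out = self.delta * k_arr
        return out if np.ndim(k) else float(out)


def from_delta_hat(
    delta_hat: float, alpha_max: float, rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
) -> PathogenProcess:
    """Build a process from the scaled divergence ``delta_hat``."""
    return PathogenProcess(delta_hat / alpha_max, rel_sd, drift_scaling)


def sample_antigenic_distance(
    process: PathogenProcess, k: int, rng: np.random.Generator
) -> float:
    """Draw the antigenic distance after ``k`` rounds of drift.

    ``k = 0`` returns exactly 0 (the pathogen at the reference round).
    Otherwise the draw is Normal(mean, rel_sd * mean) with negative
    draws rejected and redrawn, which preserves the stated relative
    width (a >5-sigma event for the default ``rel_sd``).
    """
    if k < 0 or int(k) != k:
        raise ValueError("k must be a nonnegative integer")
    if k == 0:
        return 0.0
    mean = process.mean_distance(k)
    if mean == 0.0:
        return 0.0
    sd = process.rel_sd * mean
    d = rng.normal(mean, sd)
    while d < 0:
        d = rng.normal(mean, sd)
    return float(d)


def divergence_grid(
    delta_hat_lo: float,
    delta_hat_hi: float,
    n: int,
    alpha_max: float,
    *,
    uniform: bool = False,
    rng: np.random.Generator | None = None,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
) -> list[PathogenProcess]:
    """Processes with scaled divergences spanning an interval.

    Evenly spaced over ``[lo, hi]`` by default; with ``uniform=True``
    the ``n`` values are drawn uniformly at random instead (as used for
    mixtures of pathogens with unknown evolutionary rates).
    """
    if delta_hat_lo < 0 or delta_hat_hi < delta_hat_lo:
        raise ValueError("need 0 <= lo <= hi")
    if n < 1:
        raise ValueError("n must be >= 1")
    if uniform:
        if rng is None:
            raise ValueError("uniform sampling needs an rng")
        dhats = rng.uniform(delta_hat_lo, delta_hat_hi, size=n)
    else:
        dhats = np.linspace(delta_hat_lo, delta_hat_hi, n) if n > 1 else np.array(
            [delta_hat_lo]
        )
    return [
        from_delta_hat(dh, alpha_max, rel_sd, drift_scaling) for dh in dhats
    ]


def trajectory_frame(
    process: PathogenProcess, n_rounds: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample a drift trajectory as a tidy table (round, k, distance)."""
    rows = [
        (i, i, sample_antigenic_distance(process, i, rng))
        for i in range(n_rounds + 1)
    ]
    return pd.DataFrame(rows, columns=["round", "k", "distance"])
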
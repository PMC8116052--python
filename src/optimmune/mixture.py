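"""Multi-specificity (mixture) memory strategies.

A mixture strategy stores, at the primary infection, one memory
receptor for each of ``n_m`` specificities ``alpha_i``, all centered
on the infecting antigen.  Recognition pools the receptors: the
probability of a memory response is

    P_mem = 1 - prod_i exp(-E_i * beta) = 1 - exp(-beta_tilde * Ebar)

with ``Ebar`` the mean affinity over the repertoire and ``beta_tilde =
n_m * beta`` the effective deliberation factor.  When memory responds,
the responding receptor is drawn with probability proportional to its
affinity.  The specificity vector is optimized by stochastic gradient
ascent of the net utility averaged over pathogens whose divergences
are drawn from a broad range -- the immune system does not know in
advance how fast its next pathogen evolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fast import mixture_objective_batch
from ._tables import get_table
from .decision import DeliberationCost
from .kernels import AffinityKernel, binding_affinity

__all__ = [
    "MixtureStrategy",
    "MixtureEnsemble",
    "mixture_recognition",
    "select_responder",
    "mixture_objective",
    "gradient_ascent",
    "optimize_mixture",
    "usage_probability",
    "histogram_modes",
    "dominant_modes",
]


@dataclass(frozen=True)
class MixtureStrategy:
    """A repertoire of ``n_m`` memory specificities with shared beta."""

    alphas: np.ndarray
    beta: float
    alpha_max: float = 4.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.alphas, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("alphas must be a nonempty 1-D vector")
        if np.any(arr < 0) or np.any(arr > self.alpha_max):
            raise ValueError("alphas must lie in [0, alpha_max]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        object.__setattr__(self, "alphas", arr)

    @property
    def n_m(self) -> int:
        return self.alphas.size

    @property
    def beta_tilde(self) -> float:
        """Effective deliberation factor, extensive in repertoire size."""
        return self.n_m * self.beta


@dataclass
class MixtureEnsemble:
    """Pooled results of repeated mixture optimizations."""

    alpha_vectors: list[np.ndarray]
    alpha_max: float
    bin_width: float = 0.05

    def pooled_alpha_hats(self, functional_only: bool = True) -> np.ndarray:
        pooled = np.concatenate(self.alpha_vectors) / self.alpha_max
        if functional_only:
            pooled = pooled[pooled > 0]
        return pooled

    def histogram(self, functional_only: bool = True):
        """(bin_centers, density) over scaled specificity in [0, 1]."""
        edges = np.arange(0.0, 1.0 + self.bin_width / 2, self.bin_width)
        counts, _ = np.histogram(
            self.pooled_alpha_hats(functional_only), bins=edges)
        dens = counts / max(counts.sum(), 1)
        return 0.5 * (edges[:-1] + edges[1:]), dens


def mixture_recognition(
    strategy: MixtureStrategy, kernel_family: AffinityKernel, d: float
) -> tuple[float, float]:
    """(P_mem, mean affinity Ebar) of the pooled repertoire at distance d."""
    if d < 0:
        raise ValueError("d must be >= 0")
    es = np.array([
        binding_affinity(kernel_family.with_alpha(a), d)
        for a in strategy.alphas
    ])
    ebar = float(es.mean())
    p_mem = float(-np.expm1(-strategy.beta_tilde * ebar))
    return p_mem, ebar


def select_responder(affinities, rng: np.random.Generator) -> int:
    """Index of the responding receptor, drawn proportional to affinity."""
    e = np.asarray(affinities, dtype=float)
    total = e.sum()
    if total <= 0 or np.any(e < 0):
        raise ValueError("need at least one positive affinity")
    return int(rng.choice(e.size, p=e / total))


_SHAPE_TABLES: dict[float, np.ndarray] = {}
_SHAPE_N = 6145  # a in [0, 6], linear interpolation


def _shape_table(theta: float) -> np.ndarray:
    key = round(float(theta), 10)
    if key not in _SHAPE_TABLES:
        a = np.linspace(0.0, 6.0, _SHAPE_N)
        if theta == 0.0:
            _SHAPE_TABLES[key] = np.ones(_SHAPE_N)
        else:
            _SHAPE_TABLES[key] = np.exp(-(a ** theta))
    return _SHAPE_TABLES[key]


_SHAPE_INV_DA = (_SHAPE_N - 1) / 6.0


def _draw_divergences(
    rng: np.random.Generator, n_antigens: int, delta_hat_range: tuple[float, float],
    alpha_max: float,
) -> np.ndarray:
    lo, hi = delta_hat_range
    return rng.uniform(lo, hi, size=n_antigens) / alpha_max


def mixture_objective(
    strategy: MixtureStrategy,
    kernel_family: AffinityKernel,
    delta_hat_range: tuple[float, float],
    n_antigens: int,
    L: int,
    rng: np.random.Generator,
    cost: DeliberationCost | None = None,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
    beta_max: float = 10.0,
) -> float:
    """Mean net utility per encounter over a mixture of pathogens.

    Each antigen lineage carries its own divergence (uniform over the
    scaled range) and is followed for ``L`` encounters.
    """
    if n_antigens < 1 or L < 2:
        raise ValueError("need n_antigens >= 1 and L >= 2")
    if cost is None:
        cost = DeliberationCost(form="none")
    deltas = _draw_divergences(rng, n_antigens, delta_hat_range,
                               kernel_family.alpha_max)
    z = rng.standard_normal((n_antigens, L))
    table = get_table(kernel_family.theta)
    out = np.empty(1)
    beta_hat = strategy.beta_tilde / beta_max
    mixture_objective_batch(
        np.ascontiguousarray(strategy.alphas[None, :]),
        strategy.beta_tilde, kernel_family.alpha_max, kernel_family.e_max,
        kernel_family.theta, cost.omega_hat(beta_hat),
        deltas, rel_sd, drift_scaling == "sqrt", L, z,
        _shape_table(kernel_family.theta), _SHAPE_INV_DA,
        *table.coarse_args, out,
    )
    return float(out[0])


def gradient_ascent(
    eval_batch,
    x0,
    lo: float,
    hi: float,
    epsilon: float,
    n_steps: int,
    n_probe: int,
    probe_sd: float,
    rng: np.random.Generator,
    return_trace: bool = False,
):
    """Generic stochastic gradient ascent with regression gradients.

    ``eval_batch(vectors, rng)`` evaluates the objective at a batch of
    parameter vectors (the current point is row 0) under shared noise.
    The local gradient is the least-squares slope of the objective
    differences against the probe displacements.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    if n_probe < dim + 1:
        raise ValueError("n_probe must be at least dim + 1 for the fit")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    trace = np.empty(n_steps)
    for step in range(n_steps):
        eta = rng.normal(0.0, probe_sd, size=(n_probe, dim))
        probes = np.clip(x[None, :] + eta, lo, hi)
        vecs = np.ascontiguousarray(np.vstack([x[None, :], probes]))
        obj = eval_batch(vecs, rng)
        dy = obj[1:] - obj[0]
        dx = probes - x[None, :]
        grad, *_ = np.linalg.lstsq(dx, dy, rcond=None)
        x = np.clip(x + epsilon * grad, lo, hi)
        trace[step] = obj[0]
    if return_trace:
        return x, trace
    return x


def optimize_mixture(
    initial_alphas,
    kernel_family: AffinityKernel,
    beta: float,
    delta_hat_range: tuple[float, float] = (0.0, 1.6),
    epsilon: float = 0.1,
    n_steps: int = 300,
    n_probe: int = 30,
    n_antigens: int = 50,
    L: int = 40,
    rng: np.random.Generator | None = None,
    probe_sd_frac: float = 0.10,
    cost: DeliberationCost | None = None,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
    beta_max: float = 10.0,
    return_trace: bool = False,
):
    """Stochastic gradient ascent on the specificity vector.

    Each step evaluates the objective at the current vector and at
    ``n_probe`` Gaussian perturbations (SD ``probe_sd_frac *
    alpha_max``) under shared pathogen draws, fits the local gradient
    by least squares and takes a step of size ``epsilon`` along it,
    clipping components to [0, alpha_max].
    """
    alphas = np.array(initial_alphas, dtype=float)
    n_m = alphas.size
    if rng is None:
        rng = np.random.default_rng()
    if cost is None:
        cost = DeliberationCost(form="none")
    alpha_max = kernel_family.alpha_max
    table = get_table(kernel_family.theta)
    beta_tilde = n_m * beta
    omega = cost.omega_hat(beta_tilde / beta_max)
    # the antigen panel is fixed for the whole optimization; only the
    # drift trajectories are redrawn each step
    deltas = _draw_divergences(rng, n_antigens, delta_hat_range, alpha_max)

    def eval_batch(vecs: np.ndarray, step_rng: np.random.Generator) -> np.ndarray:
        z = step_rng.standard_normal((n_antigens, L))
        out = np.empty(vecs.shape[0])
        mixture_objective_batch(
            vecs, beta_tilde, alpha_max, kernel_family.e_max,
            kernel_family.theta, omega, deltas, rel_sd,
            drift_scaling == "sqrt", L, z,
            _shape_table(kernel_family.theta), _SHAPE_INV_DA,
            *table.coarse_args, out,
        )
        return out

    return gradient_ascent(
        eval_batch, alphas, 0.0, alpha_max, epsilon, n_steps, n_probe,
        probe_sd_frac * alpha_max, rng, return_trace)


def usage_probability(
    ensemble: MixtureEnsemble,
    kernel_family: AffinityKernel,
    beta: float,
    delta_hat_range: tuple[float, float] = (0.0, 1.6),
    n_test: int = 500,
    L: int = 40,
    rng: np.random.Generator | None = None,
    rel_sd: float = 0.05,
    drift_scaling: str = "sqrt",
) -> pd.DataFrame:
    """Conditional usage P(use alpha | produce alpha), binned.

    Each test pathogen is assigned one optimized repertoire from the
    ensemble and followed for ``L`` encounters; a stored receptor
    counts as used if it responds at least once.  Bins with no
    produced receptors report NaN.
    """
    if not ensemble.alpha_vectors:
        raise ValueError("ensemble is empty")
    if rng is None:
        rng = np.random.default_rng()
    bw = ensemble.bin_width
    edges = np.arange(0.0, 1.0 + bw / 2, bw)
    produced = np.zeros(edges.size - 1)
    used = np.zeros(edges.size - 1)
    alpha_max = kernel_family.alpha_max
    theta = kernel_family.theta
    n_rep = len(ensemble.alpha_vectors)
    for t in range(n_test):
        alphas = ensemble.alpha_vectors[t % n_rep]
        n_m = alphas.size
        beta_tilde = n_m * beta
        dh = rng.uniform(*delta_hat_range)
        delta = dh / alpha_max
        bins = np.clip(np.digitize(alphas / alpha_max, edges) - 1,
                       0, edges.size - 2)
        produced_now = np.bincount(bins, minlength=edges.size - 1)
        produced += produced_now
        was_used = np.zeros(n_m, dtype=bool)
        for i in range(1, L):
            kk = np.sqrt(i) if drift_scaling == "sqrt" else i
            d = max(delta * kk * (1.0 + rel_sd * rng.standard_normal()), 0.0)
            # affinity of each slot to the drifted antigen
            if theta == 0:
                es = kernel_family.e_max * alphas / alpha_max
            else:
                es = kernel_family.e_max * (alphas / alpha_max) * np.exp(
                    -((alphas * d) ** theta))
            ebar = es.mean()
            pm = -np.expm1(-beta_tilde * ebar)
            if rng.uniform() < pm and es.sum() > 0:
                was_used[select_responder(es, rng)] = True
        used += np.bincount(bins[was_used], minlength=edges.size - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(produced > 0, used / np.maximum(produced, 1), np.nan)
    return pd.DataFrame({
        "alpha_hat_bin": 0.5 * (edges[:-1] + edges[1:]),
        "produced": produced, "used": used, "usage": curve,
    })


def dominant_modes(centers: np.ndarray, density: np.ndarray, k: int = 2,
                   smooth_passes: int = 1) -> list[float]:
    """Locations of the ``k`` highest-mass peaks of a binned distribution.

    For a distribution claimed to be k-modal this identifies *the*
    modes, ignoring smaller wiggles that `histogram_modes` would also
    report.  Returned sorted by location.
    """
    c = np.asarray(centers, dtype=float)
    h = np.asarray(density, dtype=float)
    for _ in range(smooth_passes):
        pad = np.concatenate([h[:1], h, h[-1:]])
        h = 0.25 * pad[:-2] + 0.5 * pad[1:-1] + 0.25 * pad[2:]
    padded = np.concatenate([[-np.inf], h, [-np.inf]])
    peaks = [
        (h[i], float(c[i])) for i in range(h.size)
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]
    ]
    peaks.sort(reverse=True)
    return sorted(loc for _, loc in peaks[:k])


def histogram_modes(centers: np.ndarray, density: np.ndarray,
                    min_mass: float | None = None,
                    smooth_passes: int = 1) -> list[float]:
    """Locations of local maxima of a binned distribution.

    The histogram is lightly smoothed (a [1,2,1]/4 kernel per pass)
    before peak-finding so single-bin sampling noise does not register
    as a mode; boundary bins count as candidate modes.  Peaks whose
    smoothed mass falls below ``min_mass`` -- by default the uniform
    density 1/n_bins, the level of a featureless histogram -- are
    ignored.  Returned sorted by location.
    """
    c = np.asarray(centers, dtype=float)
    h = np.asarray(density, dtype=float)
    if min_mass is None:
        min_mass = 1.0 / h.size
    for _ in range(smooth_passes):
        pad = np.concatenate([h[:1], h, h[-1:]])
        h = 0.25 * pad[:-2] + 0.5 * pad[1:-1] + 0.25 * pad[2:]
    padded = np.concatenate([[-np.inf], h, [-np.inf]])
    modes = [
        float(c[i]) for i in range(h.size)
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]
        and h[i] >= min_mass
    ]
    return sorted(modes)
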
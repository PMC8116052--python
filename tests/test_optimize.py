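"""Grid-search optimizer: argmax contracts and scan behavior."""

import numpy as np
import pytest

from optimmune import (
    DeliberationCost, PathogenProcess, Strategy, divergence_scan,
    lifetime_scan, optimize_strategy, simulate_lifetime,
)


def _optimize(kernel, delta_hat, cost, seed=1, **kw):
    proc = PathogenProcess(delta_hat / kernel.alpha_max)
    return optimize_strategy(kernel, proc, cost,
                             rng=np.random.default_rng(seed), **kw)


class TestOptimizeStrategy:
    def test_conserved_antigen_no_cost_argmax(self, gaussian_kernel, no_cost):
        """With no drift and no cost, net utility increases in both
        specificity and deliberation: the argmax is the corner (1, 1)."""
        res = _optimize(gaussian_kernel, 0.0, no_cost,
                        grid=(15, 15), L=20, n_ensembles=40)
        assert res.alpha_hat_star == 1.0
        assert res.beta_hat_star == 1.0

    def test_argmax_attains_surface_maximum(self, gaussian_kernel,
                                            linear_cost):
        res = _optimize(gaussian_kernel, 0.3, linear_cost,
                        grid=(12, 12), L=20, n_ensembles=40)
        assert res.u_net_star * res.L == pytest.approx(
            res.surface["u_net_total"].max())

    def test_hopeless_pathogen_shuts_memory_down(self, gaussian_kernel):
        # extreme drift with high cost: the optimum abandons memory
        cost = DeliberationCost("quadratic", 1.0)
        res = _optimize(gaussian_kernel, 2.5, cost,
                        grid=(12, 12), L=20, n_ensembles=40)
        assert res.alpha_hat_star == 0.0
        assert res.beta_hat_star == 0.0

    def test_reproducible_given_seed(self, gaussian_kernel, linear_cost):
        a = _optimize(gaussian_kernel, 0.2, linear_cost, seed=5,
                      grid=(10, 10), L=15, n_ensembles=30)
        b = _optimize(gaussian_kernel, 0.2, linear_cost, seed=5,
                      grid=(10, 10), L=15, n_ensembles=30)
        assert (a.surface["u_net_total"] == b.surface["u_net_total"]).all()

    def test_surface_shape_and_grid_validation(self, gaussian_kernel,
                                               linear_cost):
        res = _optimize(gaussian_kernel, 0.2, linear_cost,
                        grid=(6, 8), L=10, n_ensembles=10)
        assert len(res.surface) == 48
        with pytest.raises(ValueError):
            _optimize(gaussian_kernel, 0.2, linear_cost, grid=(1, 5))

    def test_batch_kernel_matches_reference_simulator(
            self, gaussian_kernel, linear_cost):
        """The compiled sweep and the per-round python simulator are the
        same model: their ensemble means agree within Monte-Carlo error."""
        proc = PathogenProcess(0.05)
        res = optimize_strategy(
            gaussian_kernel, proc, linear_cost, grid=(2, 5), L=25,
            n_ensembles=600, rng=np.random.default_rng(3))
        cell = res.surface.iloc[9]  # alpha_hat=1, beta_hat=1
        assert cell["alpha_hat"] == 1.0 and cell["beta_hat"] == 1.0
        strat = Strategy(4.0, 10.0)
        rng = np.random.default_rng(17)
        vals = [
            simulate_lifetime(strat, gaussian_kernel, proc, linear_cost,
                              25, rng).mean_net_utility
            for _ in range(400)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - cell["u_net_scored"]) < 4 * se


class TestScans:
    def test_divergence_scan_is_deterministic_and_ordered(
            self, gaussian_kernel, linear_cost):
        df = divergence_scan(gaussian_kernel, linear_cost, [0.1, 0.4],
                             grid=(12, 12), L=20, n_ensembles=40, seed=2)
        df2 = divergence_scan(gaussian_kernel, linear_cost, [0.1, 0.4],
                              grid=(12, 12), L=20, n_ensembles=40, seed=2)
        assert (df["alpha_hat_star"] == df2["alpha_hat_star"]).all()
        # cross-reactivity increases with drift
        assert df["alpha_hat_star"].iloc[1] <= df["alpha_hat_star"].iloc[0]

    def test_lifetime_scan_short_life_prefers_specific(
            self, gaussian_kernel, linear_cost):
        proc = PathogenProcess(0.35 / 4.0)
        df, c_star = lifetime_scan(
            gaussian_kernel, proc, linear_cost, [2, 20],
            grid=(12, 12), n_ensembles=60, seed=4,
            ensemble_budget=2000, max_ensembles=500)
        assert df["alpha_hat_star"].iloc[0] >= df["alpha_hat_star"].iloc[1]
        assert c_star in df["L"].values


class TestPhaseSurface:
    def test_three_regimes_emerge(self, gaussian_kernel, linear_cost):
        """Across slow, moderate and fast drift the (delta_hat,
        beta_hat) plane splits into equilibrium-memory,
        non-equilibrium-memory and equilibrium-naive regions."""
        from optimmune import phase_surface

        df = phase_surface(gaussian_kernel, linear_cost,
                           [0.05, 0.4, 1.2], grid=(10, 10), L=30,
                           n_ensembles=60, seed=6)
        regimes = set(df["regime"])
        assert regimes == {"equilibrium memory", "non-equilibrium memory",
                           "equilibrium naive"}
        # slow drift at high deliberation is equilibrium memory;
        # fast drift is naive-dominated
        slow = df[(df.delta_hat == 0.05) & (df.beta_hat == 1.0)]
        assert (slow["regime"] == "equilibrium memory").all()
        fast = df[(df.delta_hat == 1.2) & (df.beta_hat <= 0.5)]
        assert (fast["regime"] == "equilibrium naive").all()
        assert df["k_rel"].max() == 1.0
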
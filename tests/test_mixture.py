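"""Mixture strategies: pooled recognition, selection, and the optimizer."""

import numpy as np
import pytest

from optimmune import (
    AffinityKernel, MixtureEnsemble, MixtureStrategy, PathogenProcess,
    Strategy, binding_affinity, gradient_ascent, histogram_modes,
    mixture_objective, mixture_recognition, optimize_mixture,
    recognition_probabilities, select_responder, simulate_lifetime,
    usage_probability,
)
from optimmune.decision import DeliberationCost


class TestMixtureRecognition:
    def test_product_and_exponential_forms_agree(self, gaussian_kernel, rng):
        """1 - prod(1 - p_i) == 1 - exp(-beta_tilde * Ebar) identically."""
        for _ in range(20):
            alphas = rng.uniform(0.0, 4.0, size=8)
            beta = rng.uniform(0.01, 0.5)
            d = rng.uniform(0.0, 1.5)
            strat = MixtureStrategy(alphas, beta, 4.0)
            p_mem, _ = mixture_recognition(strat, gaussian_kernel, d)
            prod = 1.0
            for a in alphas:
                e = binding_affinity(gaussian_kernel.with_alpha(a), d)
                prod *= np.exp(-e * beta)
            assert p_mem == pytest.approx(1.0 - prod, abs=1e-12)

    def test_single_component_reduces_to_single_memory(self, gaussian_kernel):
        strat = MixtureStrategy(np.array([3.0]), 2.0, 4.0)
        p_mix, _ = mixture_recognition(strat, gaussian_kernel, 0.4)
        p_single, _ = recognition_probabilities(
            gaussian_kernel.with_alpha(3.0), 0.4, 2.0)
        assert p_mix == pytest.approx(p_single, rel=1e-12)

    def test_identical_components_pool_their_load(self, gaussian_kernel):
        strat = MixtureStrategy(np.full(5, 2.0), 0.3, 4.0)
        p_mix, _ = mixture_recognition(strat, gaussian_kernel, 0.2)
        e = binding_affinity(gaussian_kernel.with_alpha(2.0), 0.2)
        assert p_mix == pytest.approx(1.0 - np.exp(-5 * 0.3 * e), rel=1e-12)

    def test_beta_tilde_is_extensive(self):
        strat = MixtureStrategy(np.ones(20), 0.1)
        assert strat.beta_tilde == pytest.approx(2.0)


class TestSelectResponder:
    def test_single_positive_entry(self, rng):
        assert select_responder([0.0, 0.7, 0.0], rng) == 1

    def test_all_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            select_responder([0.0, 0.0], rng)

    def test_selection_frequencies(self, rng):
        # affinities 2:1 give 2/3 : 1/3 response rates
        counts = np.zeros(2)
        n = 6000
        for _ in range(n):
            counts[select_responder([2e-3, 1e-3], rng)] += 1
        p = counts[0] / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(p - 2.0 / 3.0) < 3 * se


class TestMixtureObjective:
    def test_zero_deliberation_is_pure_naive(self, gaussian_kernel, rng):
        strat = MixtureStrategy(np.linspace(0.5, 4.0, 10), 0.0, 4.0)
        obj = mixture_objective(strat, gaussian_kernel, (0.0, 1.6), 20, 10,
                                rng)
        assert obj == 0.0  # no cost, memory never engaged

    def test_single_component_matches_lifetime_simulator(
            self, gaussian_kernel):
        """n_m=1 mixtures follow the single-memory model: the two
        independent implementations agree within Monte-Carlo error."""
        dh = 0.3
        strat = MixtureStrategy(np.array([4.0]), 5.0, 4.0)
        objs = [
            mixture_objective(strat, gaussian_kernel, (dh, dh), 1, 30,
                              np.random.default_rng(s))
            for s in range(200)
        ]
        single = Strategy(4.0, 5.0)
        proc = PathogenProcess(dh / 4.0)
        rng = np.random.default_rng(999)
        ref = [
            simulate_lifetime(single, gaussian_kernel, proc,
                              DeliberationCost("none"), 30, rng
                              ).total_net_utility / 30.0
            for _ in range(200)
        ]
        se = np.hypot(np.std(objs, ddof=1) / np.sqrt(len(objs)),
                      np.std(ref, ddof=1) / np.sqrt(len(ref)))
        assert abs(np.mean(objs) - np.mean(ref)) < 3 * se

    def test_variance_shrinks_with_antigens(self, gaussian_kernel):
        strat = MixtureStrategy(np.linspace(0.5, 4.0, 10), 0.1, 4.0)
        small = [mixture_objective(strat, gaussian_kernel, (0.0, 1.6), 5, 20,
                                   np.random.default_rng(s))
                 for s in range(60)]
        big = [mixture_objective(strat, gaussian_kernel, (0.0, 1.6), 50, 20,
                                 np.random.default_rng(s))
               for s in range(60)]
        assert np.var(big) < np.var(small)


class TestGradientAscent:
    def test_quadratic_oracle_converges(self, rng):
        """On a known concave objective the regression-gradient ascent
        finds the maximum within a step size."""
        target = np.array([1.2, 3.1, 0.4])

        def eval_batch(vecs, _rng):
            return -np.sum((vecs - target) ** 2, axis=1)

        x = gradient_ascent(eval_batch, np.array([3.0, 0.5, 2.0]),
                            -5.0, 5.0, epsilon=0.1, n_steps=200,
                            n_probe=10, probe_sd=0.2, rng=rng)
        assert np.max(np.abs(x - target)) < 0.1

    def test_optimizer_improves_the_objective(self, gaussian_kernel, rng):
        # score initial and optimized vectors on one large common
        # antigen sample so the comparison is not drowned in noise
        init = rng.uniform(0.0, 4.0, 12)
        final = optimize_mixture(
            init, gaussian_kernel, 0.1, (0.0, 1.6), n_steps=150,
            n_probe=20, n_antigens=30, L=20, rng=rng)

        def score(alphas):
            return mixture_objective(
                MixtureStrategy(alphas, 0.1, 4.0), gaussian_kernel,
                (0.0, 1.6), 400, 20, np.random.default_rng(777))

        assert score(final) >= score(init) - 1e-3

    def test_probe_count_validation(self, rng):
        with pytest.raises(ValueError):
            gradient_ascent(lambda v, r: np.zeros(len(v)), np.zeros(5),
                            0, 1, 0.1, 10, n_probe=3, probe_sd=0.1, rng=rng)


class TestUsageProbability:
    def test_usage_curve_basics(self, gaussian_kernel, rng):
        # one repertoire mixing dead (alpha=0), cross-reactive and
        # maximally specific receptors
        vecs = [np.array([0.0, 0.0, 2.0, 2.0, 3.8, 3.8])]
        ens = MixtureEnsemble(vecs, 4.0, 0.25)
        df = usage_probability(ens, gaussian_kernel, beta=0.4,
                               delta_hat_range=(0.0, 1.6), n_test=150,
                               L=20, rng=rng)
        first = df.iloc[0]
        assert first["produced"] > 0 and first["usage"] == 0.0  # alpha=0 unused
        assert df["usage"].max() <= 1.0
        assert np.nansum(df["used"]) > 0
        # cross-reactive receptors answer more infections per stored
        # copy than maximally specific ones under the broad drift mix
        usage_cross = df.loc[df.alpha_hat_bin == 0.625, "usage"].iloc[0]
        usage_specific = df.loc[df.alpha_hat_bin == 0.875, "usage"].iloc[0]
        assert usage_cross > usage_specific

    def test_empty_ensemble_rejected(self, gaussian_kernel, rng):
        with pytest.raises(ValueError):
            usage_probability(MixtureEnsemble([], 4.0), gaussian_kernel,
                              0.1, rng=rng)


class TestHistogramModes:
    def test_two_separated_peaks(self):
        c = np.linspace(0.025, 0.975, 20)
        h = np.zeros(20)
        h[9] = 0.3   # peak near 0.475
        h[19] = 0.4  # boundary peak near 0.975
        h[4] = 0.01  # below mass threshold, ignored
        modes = histogram_modes(c, h)
        assert modes == pytest.approx([0.475, 0.975])

    def test_strategy_validation(self):
        with pytest.raises(ValueError):
            MixtureStrategy(np.array([5.0]), 0.1, 4.0)
        with pytest.raises(ValueError):
            MixtureStrategy(np.array([1.0]), -0.1, 4.0)
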
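"""Decision rule: recognition, utilities, and max-entropy consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optimmune import (
    AffinityKernel, DeliberationCost, KineticParameters, NEVER_MEMORY,
    Strategy, decision_distribution, deliberation_time,
    recognition_probabilities, utilities, utility_gap_from_recognition,
)


class TestDeliberationTime:
    @pytest.mark.parametrize("tau0,t_half,b,expected", [
        (1.0, 0.5, 2.0, 1.5),                    # lower end of the 1.5-5 d range
        (3.0, 1.0, 1.0, 3.0),                    # no recruitment advantage
        (2.0, 2.0, 3.0, 2.0 + 2.0 * math.log2(3.0)),  # upper end, ~5.17 d
    ])
    def test_values(self, tau0, t_half, b, expected):
        kp = KineticParameters(tau0, t_half, b)
        assert deliberation_time(kp) == pytest.approx(expected, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            KineticParameters(0.0, 0.5, 2.0)


class TestRecognition:
    def test_no_deliberation_always_naive(self, gaussian_kernel):
        p_mem, p_naive = recognition_probabilities(gaussian_kernel, 0.3, 0.0)
        assert (p_mem, p_naive) == (0.0, 1.0)

    def test_half_recognition_at_log2_load(self):
        k = AffinityKernel(4.0, 2.0, 4.0, 1.0)
        beta = math.log(2.0)  # E(0)=1, so E*beta = ln 2
        p_mem, p_naive = recognition_probabilities(k, 0.0, beta)
        assert p_mem == pytest.approx(0.5, rel=1e-12)
        assert p_naive == pytest.approx(0.5, rel=1e-12)

    def test_saturated_memory(self, gaussian_kernel):
        p_mem, p_naive = recognition_probabilities(gaussian_kernel, 0.0, 10.0)
        assert p_naive == pytest.approx(math.exp(-10.0), rel=1e-12)
        assert p_mem + p_naive == pytest.approx(1.0, abs=1e-15)

    @given(d=st.floats(0.0, 2.0), beta=st.floats(0.01, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, gaussian_kernel, d, beta):
        p_mem, p_naive = recognition_probabilities(gaussian_kernel, d, beta)
        assert 0.0 <= p_mem <= 1.0
        assert p_mem + p_naive == pytest.approx(1.0, abs=1e-12)


class TestUtilities:
    def test_no_cost(self, gaussian_kernel, no_cost):
        u_mem, u_naive = utilities(gaussian_kernel, 0.2, 5.0, no_cost)
        assert u_naive == 0.0
        assert u_mem > 0.0

    def test_linear_cost_value(self, gaussian_kernel):
        cost = DeliberationCost("linear", 0.1)
        u_mem, u_naive = utilities(gaussian_kernel, 0.0, 2.0, cost,
                                   beta_max=10.0)
        assert u_naive == pytest.approx(-0.02, rel=1e-12)
        assert u_mem - u_naive == pytest.approx(1.0, rel=1e-12)

    def test_distant_antigen_removes_memory_advantage(self, gaussian_kernel,
                                                      linear_cost):
        u_mem, u_naive = utilities(gaussian_kernel, 50.0, 2.0, linear_cost)
        assert u_mem == pytest.approx(u_naive, abs=1e-12)

    def test_quadratic_cost_form(self):
        cost = DeliberationCost("quadratic", 0.5)
        assert cost.omega_hat(0.4) == pytest.approx(0.08)


class TestMaxEntropyRule:
    def test_indifference_gives_half(self):
        assert decision_distribution(1.0, 1.0, 5.0) == 0.5

    def test_deterministic_limit(self):
        assert decision_distribution(1.0, 0.0, 900.0) == pytest.approx(1.0)
        assert decision_distribution(0.0, 1.0, 900.0) == pytest.approx(0.0)

    def test_prior_weighted_rule(self):
        # at equal utilities the decision reduces to the prior; the
        # degenerate priors are absorbing
        assert decision_distribution(1.0, 1.0, 5.0, prior_mem=0.2) == (
            pytest.approx(0.2))
        assert decision_distribution(0.0, 3.0, 5.0, prior_mem=1.0) == 1.0
        assert decision_distribution(3.0, 0.0, 5.0, prior_mem=0.0) == 0.0
        with pytest.raises(ValueError):
            decision_distribution(0.0, 0.0, 1.0, prior_mem=1.5)

    def test_gap_examples(self):
        # E*beta = ln 2 is the indifference point
        assert utility_gap_from_recognition(math.log(2.0), 1.0) == pytest.approx(
            0.0, abs=1e-12)
        # strong memory: gap approaches E
        assert utility_gap_from_recognition(1.0, 500.0) == pytest.approx(
            1.0, rel=1e-6)
        # direct evaluation
        assert utility_gap_from_recognition(0.1, 10.0) == pytest.approx(
            math.log(math.e - 1.0) / 10.0, rel=1e-12)

    def test_never_memory_sentinel(self):
        assert utility_gap_from_recognition(0.0, 5.0) == NEVER_MEMORY

    def test_consistency_of_kinetic_and_decision_descriptions(
            self, gaussian_kernel):
        """The max-ent rule with the consistency gap reproduces the
        recognition probability to 1e-10 across the (E, beta) domain."""
        es = np.linspace(0.01, 1.0, 25)
        betas = np.linspace(0.05, 10.0, 25)
        worst = 0.0
        for e in es:
            for beta in betas:
                gap = utility_gap_from_recognition(e, beta)
                q_mem = decision_distribution(gap, 0.0, beta)
                p_mem = -math.expm1(-e * beta)
                worst = max(worst, abs(q_mem - p_mem))
        assert worst < 1e-10

    @given(e=st.floats(0.01, 1.0), beta=st.floats(0.1, 10.0),
           e2=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_gap_strictly_increasing_in_affinity(self, e, beta, e2):
        lo, hi = sorted([e, e2])
        if hi - lo > 1e-9:
            assert (utility_gap_from_recognition(hi, beta)
                    > utility_gap_from_recognition(lo, beta))


class TestStrategyTypes:
    def test_beta_bounds(self):
        with pytest.raises(ValueError):
            Strategy(alpha=2.0, beta=11.0, beta_max=10.0)
        assert Strategy(2.0, 4.0).beta_hat == pytest.approx(0.4)

    def test_cost_validation(self):
        with pytest.raises(ValueError):
            DeliberationCost("cubic", 0.1)
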
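"""Bias-model policies: traces, reduction identities, simulation."""

import numpy as np
import pytest

from optstop.agents import (
    AgentSpec,
    biased_prior_action_values,
    cost_to_sample_action_values,
    cutoff_action_values,
    cutoff_take_indicators,
    simulate_stop_positions,
)
from optstop.beliefs import init_prior
from optstop.ideal import backward_induction
from optstop.payoffs import PayoffScheme
from optstop.task import DecisionContext


class TestCutoff:
    def test_policy_trace(self):
        """With c=3, take the first best-so-far option after position 3."""
        values = np.array([3.0, 5.0, 2.0, 6.0, 4.0, 7.0])
        delta = cutoff_take_indicators(values, c=3)
        stop = next(i + 1 for i, d in enumerate(delta) if d >= 0)
        assert stop == 4  # 6 is the first best-so-far after the cut-off

    def test_no_best_so_far_forces_final_take(self):
        values = np.array([90.0, 80.0, 70.0, 60.0, 50.0, 40.0])
        delta = cutoff_take_indicators(values, c=5)
        assert (delta[:-1] < 0).all()
        assert delta[-1] == np.inf

    def test_first_position_always_sampled(self):
        ctx = DecisionContext.from_prefix([75.0], 12)
        av = cutoff_action_values(ctx, c=2)
        assert (av.q_take, av.q_sample) == (0.0, 1.0)

    def test_indicator_values(self):
        values = np.array([10.0, 50.0, 90.0, 70.0, 95.0])
        ctx = DecisionContext.from_prefix(values[:3], 5)  # t=3 > c=2, h=1
        av = cutoff_action_values(ctx, c=2)
        assert (av.q_take, av.q_sample) == (1.0, 0.0)
        ctx = DecisionContext.from_prefix(values[:4], 5)  # h=2 after 90
        av = cutoff_action_values(ctx, c=2)
        assert (av.q_take, av.q_sample) == (0.0, 1.0)

    def test_bounds_enforced(self):
        ctx = DecisionContext.from_prefix([50.0], 12)
        with pytest.raises(ValueError):
            cutoff_action_values(ctx, c=1)
        with pytest.raises(ValueError):
            cutoff_action_values(ctx, c=12)


class TestReductionIdentities:
    """Cost to Sample at C=0 and Biased Prior at delta=0 ARE the Ideal Observer."""

    def test_identities_on_random_contexts(self, market_values):
        rng = np.random.default_rng(21)
        scheme = PayoffScheme.top3_money()
        for _ in range(20):
            n = 12
            t = int(rng.integers(1, n + 1))
            prefix = market_values[rng.choice(market_values.size, t, replace=False)]
            posterior = init_prior(market_values)
            for x in prefix:
                posterior = posterior.update(float(x))
            ctx = DecisionContext.from_prefix(prefix, n)
            ideal_av = backward_induction(ctx, posterior, scheme)
            cost_av = cost_to_sample_action_values(ctx, posterior, scheme, cost=0.0)
            bias_av = biased_prior_action_values(ctx, market_values, scheme, delta=0.0)
            assert cost_av == ideal_av
            assert bias_av.q_take == ideal_av.q_take
            assert bias_av.q_sample == ideal_av.q_sample

    def test_parameter_bounds(self, market_values):
        ctx = DecisionContext.from_prefix([50.0], 12)
        posterior = init_prior(market_values).update(50.0)
        with pytest.raises(ValueError):
            cost_to_sample_action_values(ctx, posterior, PayoffScheme.continuous(), cost=1.5)
        with pytest.raises(ValueError):
            biased_prior_action_values(ctx, market_values, PayoffScheme.continuous(), delta=150.0)


class TestAgentSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            AgentSpec(model="secretary", theta=3.0)
        with pytest.raises(ValueError):
            AgentSpec(model="ideal", theta=1.0)
        with pytest.raises(ValueError):
            AgentSpec(model="cutoff")
        with pytest.raises(ValueError):
            AgentSpec(model="cost_to_sample", theta=2.0)
        with pytest.raises(ValueError):
            AgentSpec(model="biased_prior", theta=0.0, beta=200.0)


class TestSimulation:
    def test_greedy_ideal_matches_ideal_stop(self, market_values, sequences_12):
        from optstop.ideal import ideal_stop_position

        prior = init_prior(market_values)
        spec = AgentSpec(model="ideal", beta=10.0)
        scheme = PayoffScheme.continuous()
        stops = simulate_stop_positions(
            spec, sequences_12[:20], market_values, scheme, mode="greedy"
        )
        expected = [
            ideal_stop_position(s, scheme, prior)[0] for s in sequences_12[:20]
        ]
        np.testing.assert_array_equal(stops, expected)

    def test_softmax_beta_zero_is_truncated_geometric(self, market_values):
        """At beta=0 every free decision is a fair coin flip."""
        rng = np.random.default_rng(31)
        n = 12
        seqs = [
            market_values[rng.choice(market_values.size, n, replace=False)]
            for _ in range(50)
        ]
        spec = AgentSpec(model="ideal", beta=0.0)
        draws = np.concatenate(
            [
                simulate_stop_positions(
                    spec, seqs, market_values, PayoffScheme.continuous(),
                    mode="softmax", rng=np.random.default_rng(1000 + k),
                )
                for k in range(200)
            ]
        )  # 10_000 stop positions
        observed = np.bincount(draws, minlength=n + 1)[1:] / draws.size
        expected = np.array(
            [0.5**t for t in range(1, n)] + [0.5 ** (n - 1)]
        )
        tv = 0.5 * np.abs(observed - expected).sum()
        assert tv < 0.02

    def test_determinism_and_seed_requirement(self, market_values, sequences_12):
        spec = AgentSpec(model="cost_to_sample", theta=-0.2, beta=5.0)
        scheme = PayoffScheme.continuous()
        a = simulate_stop_positions(
            spec, sequences_12[:10], market_values, scheme,
            mode="softmax", rng=np.random.default_rng(5),
        )
        b = simulate_stop_positions(
            spec, sequences_12[:10], market_values, scheme,
            mode="softmax", rng=np.random.default_rng(5),
        )
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            simulate_stop_positions(
                spec, sequences_12[:2], market_values, scheme, mode="softmax"
            )
        with pytest.raises(ValueError):
            simulate_stop_positions(
                spec, sequences_12[:2], market_values, scheme, mode="argmax"
            )

    def test_stops_within_bounds(self, market_values, sequences_12):
        for model, theta in (
            ("cutoff", 5.0),
            ("cost_to_sample", 0.4),
            ("biased_prior", -30.0),
        ):
            spec = AgentSpec(model=model, theta=theta, beta=2.0)
            stops = simulate_stop_positions(
                spec, sequences_12[:15], market_values, PayoffScheme.top3_money(),
                mode="softmax", rng=np.random.default_rng(8),
            )
            assert ((stops >= 1) & (stops <= 12)).all()


class TestMonotonicity:
    """Mean greedy samples grow with each bias parameter (small grids)."""

    def test_cost_direction(self, market_values, sequences_12):
        seqs = sequences_12[:60]
        means = []
        for cost in (-0.5, 0.0, 0.5):
            spec = AgentSpec(model="cost_to_sample", theta=cost, beta=10.0)
            means.append(
                simulate_stop_positions(
                    spec, seqs, market_values, PayoffScheme.continuous(), mode="greedy"
                ).mean()
            )
        assert means[0] <= means[1] <= means[2]

    def test_delta_direction(self, market_values, sequences_12):
        seqs = sequences_12[:60]
        means = []
        for delta in (-30.0, 0.0, 30.0):
            spec = AgentSpec(model="biased_prior", theta=delta, beta=10.0)
            means.append(
                simulate_stop_positions(
                    spec, seqs, market_values, PayoffScheme.continuous(), mode="greedy"
                ).mean()
            )
        assert means[0] <= means[1] <= means[2]

    def test_cutoff_direction(self, market_values, sequences_12):
        seqs = sequences_12[:60]
        means = []
        for c in (2.0, 6.0, 11.0):
            spec = AgentSpec(model="cutoff", theta=c, beta=10.0)
            means.append(
                simulate_stop_positions(
                    spec, seqs, market_values, PayoffScheme.continuous(), mode="greedy"
                ).mean()
            )
        assert means[0] <= means[1] <= means[2]
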
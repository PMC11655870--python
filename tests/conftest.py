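"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from optstop.beliefs import predictive_pmf
from optstop.synthetic import MarketConfig, generate_market
from optstop.task import reflect_rescale


@pytest.fixture(scope="session")
def market_values():
    """A deterministic 90-price market on the 1-100 scale."""
    rng = np.random.default_rng(11)
    return reflect_rescale(generate_market(MarketConfig(), rng))


@pytest.fixture(scope="session")
def sequences_12(market_values):
    """200 matched 12-option sequences drawn without replacement."""
    rng = np.random.default_rng(12)
    return [
        market_values[rng.choice(market_values.size, 12, replace=False)]
        for _ in range(200)
    ]


# ---------------------------------------------------------------------------
# enumeration oracle for the backward-induction solver
#
# Recomputes action values under the same frozen-posterior policy by explicit
# enumeration: binomial exceedance counts are enumerated as 0/1 patterns, the
# utility recursion is an unmemoised tree walk, and rank rewards are looked up
# directly.  Only feasible for small horizons and coarse grids.


def _pattern_expectation(p_exceed: float, m: int, reward_of_count) -> float:
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=m):
        prob = 1.0
        for bit in pattern:
            prob *= p_exceed if bit else (1.0 - p_exceed)
        total += prob * reward_of_count(sum(pattern))
    return total


def oracle_action_values(prefix, n_options, posterior, scheme, cost=0.0, grid_size=5):
    """Brute-force (q_take, q_sample) at the current decision point.

    ``prefix`` is the observed values including the current option;
    ``posterior`` the belief after those observations.
    """
    prefix = np.asarray(prefix, dtype=float)
    t = prefix.size
    current = float(prefix[-1])
    pmf = predictive_pmf(posterior, grid_size)
    grid, probs = pmf.grid, pmf.probs

    if scheme.is_rank_based:
        rewards = scheme.scaled_rank_rewards(n_options)

        def reward_at_rank(rank):
            return rewards[rank - 1] if rank <= n_options else 0.0

        h = 1 + int(np.sum(prefix[:-1] > current))
        p_cur = float(probs[grid > current].sum())
        q_take = _pattern_expectation(
            p_cur, n_options - t, lambda k: reward_at_rank(h + k)
        )

        def qt_future(level, j):
            r0 = 1 + int(np.sum(prefix > grid[j]))
            p_j = float(probs[grid > grid[j]].sum())
            return _pattern_expectation(
                p_j, n_options - level, lambda k: reward_at_rank(r0 + k)
            )

    else:
        q_take = (current - 1.0) / 99.0

        def qt_future(level, j):
            return (grid[j] - 1.0) / 99.0

    def u(level, j):
        take = qt_future(level, j)
        if level == n_options:
            return take
        cont = cost + sum(probs[k] * u(level + 1, k) for k in range(grid.size))
        return max(take, cont)

    if t >= n_options:
        return q_take, None
    q_sample = cost + sum(probs[j] * u(t + 1, j) for j in range(grid.size))
    return q_take, q_sample
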
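"""Bayes-optimal ideal observer: finite-horizon backward induction.

At decision time t the observer holds a NIX posterior over the generating
distribution (updated with every option seen so far, including the current
one).  The action value of *taking* is the expected payoff of the current
option's final rank - its rank h among the observed options plus a
Binomial(N - t, p_exceed) count of future draws that beat it - or, under the
continuous scheme, simply the current value rescaled to [0, 1].  The action
value of *sampling* is the cost to sample C plus the expected utility of the
next position, obtained by backward induction from the end of the sequence
(where taking is the only action).

Lookahead uses a "frozen posterior": the posterior at time t supplies the
predictive distribution for every future position and is refreshed only when
an option is actually observed, after which the induction is recomputed.  In
the lookahead a hypothetical option of value v at position t' is ranked
against the options actually observed so far (r0(v) = 1 + #{observed > v});
draws arriving after t' contribute through the Binomial exceedance term of
its take-reward, while the intermediate lookahead positions contribute
through the recursion itself, as opportunities to stop.  The future self
observes its rank before acting, so the max over actions sits inside the
value-of-state computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .beliefs import DEFAULT_GRID_SIZE, NixBelief, predictive_pmf, value_grid
from .payoffs import PayoffScheme, expected_rank_reward
from .task import DecisionContext, OptionSequence, relative_ranks


@dataclass(frozen=True)
class ActionValues:
    """Q-values of the two available actions; ``q_sample`` is None at the
    final position, where taking is the only action."""

    q_take: float
    q_sample: float | None = None

    @property
    def delta(self) -> float:
        """q_take - q_sample (take advantage); +inf at the forced final take."""
        if self.q_sample is None:
            return np.inf
        return self.q_take - self.q_sample


@dataclass
class SequenceTables:
    """Per-position solver inputs for one sequence.

    Row i holds the frozen-posterior quantities at position t = i + 1: the
    predictive pmf over the value grid, the strict-exceedance probability and
    observed-exceedance count per grid value, and the take Q-value of the
    option actually presented there.
    """

    grid: np.ndarray
    probs: np.ndarray  # (T, G) predictive pmf per position
    p_exceed: np.ndarray  # (T, G) P(future draw > grid value)
    n_obs_exceed: np.ndarray  # (T, G) observed values strictly above grid value
    q_take: np.ndarray  # (T,)
    n_options: int
    scheme: PayoffScheme


def _rank_qt(
    r0: np.ndarray,
    p_ex: np.ndarray,
    m_future: int,
    rewards: np.ndarray,
) -> np.ndarray:
    """Expected take-reward of a lookahead option with base rank r0 (1-based)
    and ``m_future`` draws still to come after it."""
    n_ranks = rewards.size
    qt = np.zeros_like(p_ex)
    top = int(np.nonzero(rewards)[0].max()) + 1 if rewards.any() else 0
    for rank0 in range(1, top + 1):  # base rank before future exceedances
        mask = r0 == rank0
        if not mask.any():
            continue
        p = p_ex[mask]
        total = np.zeros_like(p)
        for k in range(0, min(m_future, top - rank0) + 1):
            if rank0 + k > n_ranks:
                break
            total += (
                comb(m_future, k)
                * p**k
                * (1.0 - p) ** (m_future - k)
                * rewards[rank0 + k - 1]
            )
        qt[mask] = total
    return qt


def take_reward(context: DecisionContext, pmf, scheme: PayoffScheme) -> float:
    """Expected immediate reward (on [0, 1]) of taking the current option."""
    if scheme.is_rank_based:
        rewards = scheme.scaled_rank_rewards(context.n_options)
        p_ex = pmf.p_exceed(context.value)
        return expected_rank_reward(
            context.h, context.t, context.n_options, p_ex, rewards
        )
    return float(scheme.value_reward(context.value))


def sequence_tables(
    values,
    prior: NixBelief,
    scheme: PayoffScheme,
    grid_size: int = DEFAULT_GRID_SIZE,
    upto: int | None = None,
    n_options: int | None = None,
) -> SequenceTables:
    """Build solver tables for positions 1..upto of a sequence (default all).

    ``values`` may be just the viewed prefix of a longer sequence; pass
    ``n_options`` to set the true horizon in that case.
    """
    values = np.asarray(values, dtype=float)
    n = int(n_options) if n_options else values.size
    if n < values.size:
        raise ValueError("n_options shorter than the observed values")
    T = values.size if upto is None else min(int(upto), values.size)
    states = prior.update_sequence(values[:T])

    edges, centres = value_grid(grid_size)
    df = np.array([s.nu for s in states])[:, None]
    loc = np.array([s.mu for s in states])[:, None]
    scale = np.array(
        [np.sqrt(s.sigma2 * (1.0 + 1.0 / s.kappa)) for s in states]
    )[:, None]
    cdf = stats.t.cdf(edges[None, :], df=df, loc=loc, scale=scale)
    probs = np.diff(cdf, axis=1)
    totals = probs.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0
    if np.any(bad):  # far off-scale prior: fall back to uniform over the grid
        probs[bad] = 1.0 / grid_size
        totals[bad] = 1.0
    probs = probs / totals

    # strict-exceedance probability at every grid value, per position
    tail = np.cumsum(probs[:, ::-1], axis=1)[:, ::-1]
    p_ex = np.concatenate([tail[:, 1:], np.zeros((T, 1))], axis=1)

    # observed values strictly above each grid value, per position
    n_obs = np.cumsum(values[:T, None] > centres[None, :], axis=0)

    if scheme.is_rank_based:
        rewards = scheme.scaled_rank_rewards(n)
        hs = relative_ranks(values[:T])
        q_take = np.empty(T)
        for i in range(T):
            p_ex_v = float(probs[i, centres > values[i]].sum())
            q_take[i] = expected_rank_reward(int(hs[i]), i + 1, n, p_ex_v, rewards)
    else:
        q_take = np.asarray(scheme.value_reward(values[:T]), dtype=float)

    return SequenceTables(
        grid=centres,
        probs=probs,
        p_exceed=p_ex,
        n_obs_exceed=n_obs,
        q_take=q_take,
        n_options=n,
        scheme=scheme,
    )


def q_sample_from_tables(tables: SequenceTables, cost: float = 0.0) -> np.ndarray:
    """Sampling action values at each tabulated position; NaN at position N."""
    T, n = tables.q_take.size, tables.n_options
    scheme = tables.scheme
    q_sample = np.full(T, np.nan)
    if scheme.is_rank_based:
        rewards = scheme.scaled_rank_rewards(n)
    else:
        w_cont = np.asarray(scheme.value_reward(tables.grid), dtype=float)
    for i in range(T):
        t = i + 1
        if t >= n:
            break
        probs = tables.probs[i]
        if scheme.is_rank_based:
            r0 = 1 + tables.n_obs_exceed[i]
            p_ex = tables.p_exceed[i]
            u = _rank_qt(r0, p_ex, 0, rewards)  # forced take at position N
            for level in range(n - 1, t, -1):
                qt = _rank_qt(r0, p_ex, n - level, rewards)
                u = np.maximum(qt, cost + probs @ u)
        else:
            u = w_cont
            for _level in range(n - 1, t, -1):
                u = np.maximum(w_cont, cost + probs @ u)
        q_sample[i] = cost + probs @ u
    return q_sample


def sequence_action_values(
    values,
    prior: NixBelief,
    scheme: PayoffScheme,
    cost: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
    upto: int | None = None,
    n_options: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(q_take, q_sample) arrays over positions 1..upto of one sequence."""
    tables = sequence_tables(
        values, prior, scheme, grid_size=grid_size, upto=upto, n_options=n_options
    )
    return tables.q_take, q_sample_from_tables(tables, cost=cost)


def backward_induction(
    context: DecisionContext,
    posterior: NixBelief,
    scheme: PayoffScheme,
    cost: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ActionValues:
    """Action values at one decision point (Ideal Observer when cost = 0).

    ``posterior`` is the belief after the observed prefix (which includes the
    current option).
    """
    pmf = predictive_pmf(posterior, grid_size)
    q_take = take_reward(context, pmf, scheme)
    t, n = context.t, context.n_options
    if t >= n:
        return ActionValues(q_take=q_take, q_sample=None)
    probs = pmf.probs
    if scheme.is_rank_based:
        rewards = scheme.scaled_rank_rewards(n)
        prefix = np.asarray(context.prefix, dtype=float)
        r0 = 1 + np.sum(prefix[:, None] > pmf.grid[None, :], axis=0)
        p_ex = pmf.p_exceed_grid()
        u = _rank_qt(r0, p_ex, 0, rewards)
        for level in range(n - 1, t, -1):
            qt = _rank_qt(r0, p_ex, n - level, rewards)
            u = np.maximum(qt, cost + probs @ u)
    else:
        w = np.asarray(scheme.value_reward(pmf.grid), dtype=float)
        u = w
        for _level in range(n - 1, t, -1):
            u = np.maximum(w, cost + probs @ u)
    return ActionValues(q_take=q_take, q_sample=float(cost + probs @ u))


def ideal_stop_position(
    sequence,
    scheme: PayoffScheme,
    prior: NixBelief,
    cost: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[int, list[ActionValues]]:
    """Walk a sequence as the Ideal Observer (greedy, ties favour taking).

    Returns the stop position and the per-position action values up to and
    including the stop (the final position has no sampling option).
    """
    values = sequence.values if isinstance(sequence, OptionSequence) else sequence
    values = np.asarray(values, dtype=float)
    n = values.size
    q_take, q_sample = sequence_action_values(
        values, prior, scheme, cost=cost, grid_size=grid_size
    )
    avs = []
    stop = n
    for i in range(n):
        qs = None if i + 1 == n else float(q_sample[i])
        avs.append(ActionValues(q_take=float(q_take[i]), q_sample=qs))
        if qs is None or q_take[i] >= qs:
            stop = i + 1
            break
    return stop, avs
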
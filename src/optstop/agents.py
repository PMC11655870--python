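"""Sampling policies: the Ideal Observer and the three fitted bias models.

* ``ideal`` - the Bayes-optimal observer (zero cost to sample, unbiased prior);
* ``cutoff`` - the secretary-problem heuristic: sample until a cut-off
  position c, then take the next option that is the best seen so far.  It
  uses only relative ranks, never the prior;
* ``cost_to_sample`` - the Ideal Observer with a free cost C added to the
  reward for sampling (negative C makes sampling feel costly, driving
  undersampling; positive C the reverse);
* ``biased_prior`` - the Ideal Observer with a free constant delta added to
  the prior mean of the generating distribution (negative delta encodes
  pessimism about future options, driving undersampling).

Each model pairs its key parameter with a softmax inverse temperature beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .beliefs import DEFAULT_GRID_SIZE, NixBelief, init_prior
from .ideal import ActionValues, backward_induction, q_sample_from_tables, sequence_tables
from .payoffs import PayoffScheme
from .task import DecisionContext, relative_ranks

MODEL_IDEAL = "ideal"
MODEL_CUTOFF = "cutoff"
MODEL_COST = "cost_to_sample"
MODEL_BIASED_PRIOR = "biased_prior"

FITTED_MODELS = (MODEL_CUTOFF, MODEL_COST, MODEL_BIASED_PRIOR)

BETA_BOUNDS = (0.0, 100.0)
COST_BOUNDS = (-1.0, 1.0)
DELTA_BOUNDS = (-100.0, 100.0)


def cutoff_bounds(n_options: int) -> tuple[float, float]:
    """The cut-off must leave at least one learning sample and one choice."""
    return (2.0, float(n_options - 1))


def theta_bounds(model: str, n_options: int) -> tuple[float, float] | None:
    if model == MODEL_CUTOFF:
        return cutoff_bounds(n_options)
    if model == MODEL_COST:
        return COST_BOUNDS
    if model == MODEL_BIASED_PRIOR:
        return DELTA_BOUNDS
    if model == MODEL_IDEAL:
        return None
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class AgentSpec:
    """A model plus its two free parameters (theta, beta).

    ``theta`` is the cut-off position c, the cost to sample C, or the prior
    shift delta, depending on the model; the ideal observer has none.
    """

    model: str
    theta: float | None = None
    beta: float = 1.0
    value_kind: str = "objective"

    def __post_init__(self) -> None:
        if self.model not in (MODEL_IDEAL,) + FITTED_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == MODEL_IDEAL:
            if self.theta is not None:
                raise ValueError("the ideal observer has no key parameter")
        elif self.theta is None:
            raise ValueError(f"{self.model} requires a theta parameter")
        if not BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]:
            raise ValueError("beta outside [0, 100]")
        if self.model == MODEL_COST and not (
            COST_BOUNDS[0] <= self.theta <= COST_BOUNDS[1]
        ):
            raise ValueError("cost to sample outside [-1, 1]")
        if self.model == MODEL_BIASED_PRIOR and not (
            DELTA_BOUNDS[0] <= self.theta <= DELTA_BOUNDS[1]
        ):
            raise ValueError("prior shift outside [-100, 100]")

    def validate_for_length(self, n_options: int) -> None:
        if self.model == MODEL_CUTOFF:
            lo, hi = cutoff_bounds(n_options)
            if not lo <= round(self.theta) <= hi:
                raise ValueError(f"cut-off {self.theta} outside [{lo}, {hi}]")


def cutoff_action_values(context: DecisionContext, c: float) -> ActionValues:
    """Indicator-valued Cut Off policy at one decision point.

    (0, 1) while still inside the learning period or when the current option
    is not best-so-far; (1, 0) for the first best-so-far option after the
    cut-off.  A continuous fitted c is rounded to the nearest position.
    """
    t, n = context.t, context.n_options
    c_int = int(round(c))
    lo, hi = cutoff_bounds(n)
    if not lo <= c_int <= hi:
        raise ValueError(f"cut-off {c} outside [{lo}, {hi}]")
    if t >= n:
        return ActionValues(q_take=1.0, q_sample=None)
    if t > c_int and context.h == 1:
        return ActionValues(q_take=1.0, q_sample=0.0)
    return ActionValues(q_take=0.0, q_sample=1.0)


def cutoff_take_indicators(values, c: float, n_options: int | None = None) -> np.ndarray:
    """q_take - q_sample (+1 take / -1 sample) at each position under Cut Off.

    ``values`` may be the viewed prefix of a longer sequence of ``n_options``.
    """
    values = np.asarray(values, dtype=float)
    n = int(n_options) if n_options else values.size
    c_int = int(round(c))
    hs = relative_ranks(values)
    positions = np.arange(1, values.size + 1)
    take = (positions > c_int) & (hs == 1)
    delta = np.where(take, 1.0, -1.0)
    if values.size == n:
        delta[-1] = np.inf  # forced take at the final position
    return delta


def cost_to_sample_action_values(
    context: DecisionContext,
    posterior: NixBelief,
    scheme: PayoffScheme,
    cost: float,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ActionValues:
    """Ideal Observer machinery with a non-zero cost-to-sample C."""
    if not COST_BOUNDS[0] <= cost <= COST_BOUNDS[1]:
        raise ValueError("cost to sample outside [-1, 1]")
    return backward_induction(context, posterior, scheme, cost=cost, grid_size=grid_size)


def biased_prior_action_values(
    context: DecisionContext,
    generating_values,
    scheme: PayoffScheme,
    delta: float,
    grid_size: int = DEFAULT_GRID_SIZE,
    kappa0: float | None = None,
    nu0: float | None = None,
) -> ActionValues:
    """Ideal Observer with the prior mean shifted by delta, then updated
    normally with the observed prefix."""
    if not DELTA_BOUNDS[0] <= delta <= DELTA_BOUNDS[1]:
        raise ValueError("prior shift outside [-100, 100]")
    kwargs = {}
    if kappa0 is not None:
        kwargs["kappa0"] = kappa0
    if nu0 is not None:
        kwargs["nu0"] = nu0
    posterior = init_prior(generating_values, shift=delta, **kwargs)
    for x in context.prefix:
        posterior = posterior.update(float(x))
    return backward_induction(context, posterior, scheme, cost=0.0, grid_size=grid_size)


def agent_delta_q(
    spec: AgentSpec,
    values,
    prior_values,
    scheme: PayoffScheme,
    grid_size: int = DEFAULT_GRID_SIZE,
    kappa0: float | None = None,
    nu0: float | None = None,
    upto: int | None = None,
    n_options: int | None = None,
) -> np.ndarray:
    """q_take - q_sample at positions 1..upto of one sequence (inf at N).

    The shared entry point for simulation and likelihood evaluation; the
    cut-off model needs only ranks, the others run the induction solver.
    ``values`` may be the viewed prefix of a longer sequence of ``n_options``.
    """
    values = np.asarray(values, dtype=float)
    n = int(n_options) if n_options else values.size
    if spec.model == MODEL_CUTOFF:
        delta = cutoff_take_indicators(values, spec.theta, n_options=n)
        return delta if upto is None else delta[:upto]

    shift = spec.theta if spec.model == MODEL_BIASED_PRIOR else 0.0
    cost = spec.theta if spec.model == MODEL_COST else 0.0
    kwargs = {}
    if kappa0 is not None:
        kwargs["kappa0"] = kappa0
    if nu0 is not None:
        kwargs["nu0"] = nu0
    prior = init_prior(prior_values, shift=shift, **kwargs)
    tables = sequence_tables(
        values, prior, scheme, grid_size=grid_size, upto=upto, n_options=n
    )
    q_sample = q_sample_from_tables(tables, cost=cost)
    delta = tables.q_take - q_sample
    if tables.q_take.size == n:
        delta[-1] = np.inf  # forced take at the final position
    return delta


def simulate_stop_positions(
    spec: AgentSpec,
    sequences,
    prior_values,
    scheme: PayoffScheme,
    mode: str = "softmax",
    rng: np.random.Generator | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    kappa0: float | None = None,
    nu0: float | None = None,
) -> np.ndarray:
    """Simulate one stop position per sequence under a policy.

    ``greedy`` takes whenever q_take >= q_sample (ties favour taking);
    ``softmax`` draws each take/sample decision from the softmax of the action
    values with inverse temperature beta and requires a seeded ``rng``.
    The final position is always a forced take.
    """
    if mode not in ("greedy", "softmax"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    if mode == "softmax" and rng is None:
        raise ValueError("softmax simulation requires a random generator")
    stops = np.empty(len(sequences), dtype=int)
    for s, values in enumerate(sequences):
        values = np.asarray(values, dtype=float)
        n = values.size
        delta = agent_delta_q(
            spec, values, prior_values, scheme,
            grid_size=grid_size, kappa0=kappa0, nu0=nu0,
        )
        stop = n
        for i in range(n):
            if i + 1 == n:
                stop = n
                break
            if mode == "greedy":
                take = delta[i] >= 0
            else:
                take = rng.random() < expit(spec.beta * delta[i])
            if take:
                stop = i + 1
                break
        stops[s] = stop
    return stops
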
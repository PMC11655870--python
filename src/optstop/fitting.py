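"""Softmax choice likelihood and per-participant maximum-likelihood fitting.

Each bias model has two free parameters: its key theoretical parameter theta
(cut-off c, cost C, or prior shift delta) and the softmax inverse temperature
beta.  At every free decision the probability of taking is

    P(take) = 1 / (1 + exp(-beta * (Q_take - Q_sample)))

and the model's negative log-likelihood sums -log P(observed action) over all
free decisions (the forced take at the final position carries no term, since
only one action exists there).

Optimisation uses a derivative-free simplex search with box constraints
enforced by a smooth sinusoidal transform of the parameters, in the style of
bounded variants of fminsearch.  The cut-off position is a discrete parameter,
so it is fitted by exhaustive enumeration over the integer cut-offs with a
one-dimensional bounded simplex on beta inside each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .agents import (
    BETA_BOUNDS,
    FITTED_MODELS,
    MODEL_BIASED_PRIOR,
    MODEL_COST,
    MODEL_CUTOFF,
    AgentSpec,
    agent_delta_q,
    cutoff_bounds,
    cutoff_take_indicators,
    theta_bounds,
)
from .beliefs import DEFAULT_GRID_SIZE, DEFAULT_KAPPA0, DEFAULT_NU0, init_prior
from .ideal import q_sample_from_tables, sequence_tables
from .payoffs import PayoffScheme
from .task import ParticipantData

PROB_FLOOR = 1e-12

#: Asymptotic secretary-problem optimum: observe ~1/e of the sequence before
#: committing; 100/e rounds to 37%.  Used as the Cut Off starting value.
CUTOFF_START_FRACTION = 0.37

BETA_START = 1.0


def cutoff_start(n_options: int) -> int:
    """Starting cut-off: 37% of the sequence length, rounded to nearest."""
    return int(round(CUTOFF_START_FRACTION * n_options))


def theta_start(model: str, n_options: int) -> float:
    """Starting value of the key parameter (the optimal value for C, delta)."""
    if model == MODEL_CUTOFF:
        return float(cutoff_start(n_options))
    return 0.0


@dataclass(frozen=True)
class FitConfig:
    """Optimiser and solver settings for one fit."""

    scheme: PayoffScheme
    grid_size: int = DEFAULT_GRID_SIZE
    kappa0: float = DEFAULT_KAPPA0
    nu0: float = DEFAULT_NU0
    tol: float = 1e-6
    max_iter: int = 2000
    n_restarts: int = 1
    seed: int | None = None


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    model: str
    value_kind: str
    theta: float
    beta: float
    nll: float
    n_choices: int
    converged: bool
    n_restarts: int


def softmax_take_prob(action_values, beta: float) -> float:
    """P(take) from action values under softmax with inverse temperature beta."""
    delta = action_values.delta if hasattr(action_values, "delta") else float(action_values)
    return float(expit(beta * delta))


def _decision_log_lik(delta_q: np.ndarray, took: np.ndarray, beta: float) -> float:
    """Sum of log choice probabilities, overflow-safe and floored."""
    signed = np.where(took, delta_q, -delta_q)
    logp = log_expit(beta * signed)
    return float(np.sum(np.maximum(logp, np.log(PROB_FLOOR))))


def _free_decision_count(data: ParticipantData) -> int:
    return data.n_free_decisions


class ParticipantLikelihood:
    """Negative log-likelihood of one participant's choices under one model.

    Precomputes whatever is theta-independent: for the cost-to-sample model
    the predictive pmfs, future take-rewards and take Q-values per position
    (only the induction recursion depends on C); for the cut-off model the
    relative-rank indicators.  The biased-prior model shifts the prior itself,
    so its tables are rebuilt per theta.
    """

    def __init__(self, model: str, data: ParticipantData, config: FitConfig):
        if model not in FITTED_MODELS:
            raise ValueError(f"cannot fit model {model!r}")
        if not data.sequences:
            raise ValueError("participant has no sequences")
        self.model = model
        self.data = data
        self.config = config
        # free decisions per sequence: positions 1..stop-1 are 'sample'
        # choices, the take at stop is free only before the final position
        # (at N taking is the only action, so it carries no likelihood term)
        n = data.n_options
        self._free_upto = []
        self._took = []
        for stop, forced_ in zip(data.stops, data.forced):
            if forced_ or stop >= n:
                upto = min(stop, n) - 1
                took = np.zeros(upto, dtype=bool)
            else:
                upto = stop
                took = np.array([False] * (stop - 1) + [True], dtype=bool)
            self._free_upto.append(upto)
            self._took.append(took)
        self.n_choices = int(sum(len(t) for t in self._took))
        if self.n_choices == 0:
            raise ValueError("participant has no free decisions")

        if model == MODEL_COST:
            prior = init_prior(
                data.prior_values, kappa0=config.kappa0, nu0=config.nu0
            )
            self._tables = [
                sequence_tables(
                    values, prior, config.scheme,
                    grid_size=config.grid_size, upto=upto, n_options=n,
                )
                for values, upto in zip(data.sequences, self._free_upto)
            ]

    def nll(self, theta: float, beta: float) -> float:
        total = 0.0
        cfg = self.config
        for s, values in enumerate(self.data.sequences):
            upto = self._free_upto[s]
            if upto == 0:
                continue
            took = self._took[s]
            if self.model == MODEL_CUTOFF:
                delta = cutoff_take_indicators(
                    values, theta, n_options=self.data.n_options
                )[:upto]
            elif self.model == MODEL_COST:
                tables = self._tables[s]
                delta = tables.q_take - q_sample_from_tables(tables, cost=theta)
            else:  # biased prior
                spec = AgentSpec(model=MODEL_BIASED_PRIOR, theta=theta, beta=beta)
                delta = agent_delta_q(
                    spec, values, self.data.prior_values, cfg.scheme,
                    grid_size=cfg.grid_size, kappa0=cfg.kappa0, nu0=cfg.nu0,
                    upto=upto, n_options=self.data.n_options,
                )
            total -= _decision_log_lik(np.asarray(delta[:upto]), took, beta)
        return total


def negative_log_likelihood(
    spec: AgentSpec, data: ParticipantData, config: FitConfig
) -> float:
    """NLL of a fully specified agent on one participant's free decisions."""
    like = ParticipantLikelihood(spec.model, data, config)
    return like.nll(spec.theta, spec.beta)


# ---------------------------------------------------------------------------
# bounded simplex search (sin-transformed box constraints)


def _to_unbounded(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return np.arcsin(frac)


def _to_bounded(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * (np.sin(z) + 1.0) / 2.0


def minimize_bounded_simplex(fun, x0, bounds, tol=1e-6, max_iter=2000):
    """Nelder-Mead on sin-transformed coordinates; returns (x, f, converged)."""
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    z0 = _to_unbounded(np.asarray(x0, dtype=float), lo, hi)
    res = minimize(
        lambda z: fun(_to_bounded(z, lo, hi)),
        z0,
        method="Nelder-Mead",
        options={
            "xatol": tol,
            "fatol": tol,
            "maxiter": max_iter,
            "maxfev": max_iter,
        },
    )
    return _to_bounded(res.x, lo, hi), float(res.fun), bool(res.success)


def fit_participant(
    model: str,
    data: ParticipantData,
    config: FitConfig,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model to one participant's choices.

    Starting values follow the study protocol (beta = 1; cut-off at 37% of
    the sequence length; C = delta = 0, their optimal values).  Optional
    multi-start jitters the start uniformly inside the bounds; the best of
    all restarts is returned and never worse than the protocol start.
    """
    like = ParticipantLikelihood(model, data, config)
    n = data.n_options
    t_bounds = theta_bounds(model, n)
    b_bounds = BETA_BOUNDS
    theta0 = theta_start(model, n)

    if config.n_restarts > 1 and rng is None:
        rng = np.random.default_rng(config.seed)

    best = None
    converged_any = False
    for restart in range(max(1, config.n_restarts)):
        if restart == 0:
            start_theta, start_beta = theta0, BETA_START
        else:
            start_theta = rng.uniform(*t_bounds)
            start_beta = rng.uniform(0.1, 20.0)

        if model == MODEL_CUTOFF:
            # discrete cut-off: enumerate integer positions, 1-D simplex on beta
            lo, hi = cutoff_bounds(n)
            for c in range(int(lo), int(hi) + 1):
                x, f, ok = minimize_bounded_simplex(
                    lambda p, c=c: like.nll(float(c), p[0]),
                    [start_beta],
                    [b_bounds],
                    tol=config.tol,
                    max_iter=config.max_iter,
                )
                converged_any |= ok
                if best is None or f < best[2]:
                    best = (float(c), float(x[0]), f)
        else:
            x, f, ok = minimize_bounded_simplex(
                lambda p: like.nll(p[0], p[1]),
                [start_theta, start_beta],
                [t_bounds, b_bounds],
                tol=config.tol,
                max_iter=config.max_iter,
            )
            converged_any |= ok
            if best is None or f < best[2]:
                best = (float(x[0]), float(x[1]), f)

    theta, beta, nll = best
    return FitResult(
        participant_id=data.participant_id,
        model=model,
        value_kind=data.value_kind,
        theta=theta,
        beta=beta,
        nll=float(nll),
        n_choices=like.n_choices,
        converged=converged_any,
        n_restarts=max(1, config.n_restarts),
    )


def fit_cohort(
    participants,
    models=FITTED_MODELS,
    config: FitConfig | None = None,
    **config_kwargs,
):
    """Fit a set of models to every participant; returns a tidy DataFrame."""
    import pandas as pd

    from .comparison import bic

    if config is None:
        config = FitConfig(**config_kwargs)
    rows = []
    for data in participants:
        for model in models:
            fit = fit_participant(model, data, config)
            rows.append(
                {
                    "participant_id": fit.participant_id,
                    "model": fit.model,
                    "value_kind": fit.value_kind,
                    "theta": fit.theta,
                    "beta": fit.beta,
                    "nll": fit.nll,
                    "n_choices": fit.n_choices,
                    "bic": bic(fit.nll, k=2, n=fit.n_choices),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
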
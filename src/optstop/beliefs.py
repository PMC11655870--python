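"""Conjugate Bayesian beliefs about the option-generating distribution.

Option values are modelled as draws from a Gaussian with unknown mean and
variance under a normal-inverse-chi-squared (NIX) prior.  The prior is
initialised from the distribution of generating values (the rescaled market,
or a participant's own ratings) and updated after each newly observed option.
The posterior predictive for the next option value is a Student-t, discretised
onto a grid spanning the 1-100 rating scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import VALUE_MAX, VALUE_MIN

#: Prior-confidence defaults.  Participants view the full 90-price generating
#: distribution (rating every price twice) before the stopping task, so the
#: prior mean and variance rest on substantial experience; weak settings
#: (kappa0, nu0 of order 1) also make a shifted prior mean self-erase within a
#: few options - surprise inflates the posterior variance enough to offset the
#: pessimism - so the prior-shift parameter would no longer modulate sampling
#: monotonically through its range.
DEFAULT_KAPPA0 = 10.0
DEFAULT_NU0 = 10.0
DEFAULT_GRID_SIZE = 100


@dataclass(frozen=True)
class NixBelief:
    """Normal-inverse-chi-squared belief state.

    Parameters
    ----------
    mu : location of the mean (1-100 scale)
    kappa : pseudo-count behind the mean (> 0)
    sigma2 : scale of the variance (> 0)
    nu : degrees of freedom behind the variance (> 0)
    n : number of option values observed so far
    """

    mu: float
    kappa: float
    sigma2: float
    nu: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.nu <= 0 or self.sigma2 <= 0:
            raise ValueError("kappa, nu and sigma2 must all be positive")

    def update(self, x: float) -> "NixBelief":
        """Conjugate update after observing one option value."""
        k1 = self.kappa + 1.0
        nu1 = self.nu + 1.0
        mu1 = (self.kappa * self.mu + x) / k1
        s1 = (self.nu * self.sigma2 + (self.kappa / k1) * (x - self.mu) ** 2) / nu1
        return NixBelief(mu1, k1, s1, nu1, self.n + 1)

    def update_sequence(self, xs) -> list["NixBelief"]:
        """Belief state after each successive observation (length len(xs))."""
        states = []
        state = self
        for x in np.asarray(xs, dtype=float):
            state = state.update(float(x))
            states.append(state)
        return states

    @property
    def predictive_params(self) -> tuple[float, float, float]:
        """(df, loc, scale) of the Student-t posterior predictive."""
        scale = float(np.sqrt(self.sigma2 * (1.0 + 1.0 / self.kappa)))
        return float(self.nu), float(self.mu), scale


def init_prior(
    generating_values,
    shift: float = 0.0,
    kappa0: float = DEFAULT_KAPPA0,
    nu0: float = DEFAULT_NU0,
) -> NixBelief:
    """Initialise the prior from the mean and variance of the generating values.

    ``shift`` is the Biased Prior model's constant added to the prior mean;
    zero for the Ideal Observer.  Variance is the sample variance (ddof=1).
    """
    values = np.asarray(generating_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two generating values")
    var = float(np.var(values, ddof=1))
    if var == 0:
        raise ValueError("zero-variance generating values")
    return NixBelief(mu=float(np.mean(values)) + shift, kappa=kappa0, sigma2=var, nu=nu0)


def batch_update(prior: NixBelief, xs) -> NixBelief:
    """Closed-form NIX update on a whole batch of observations.

    Mathematically identical to folding :meth:`NixBelief.update` over the
    batch in any order; kept as an independent code path so the sequential
    recursion can be checked against it.
    """
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    if n == 0:
        return prior
    xbar = float(np.mean(xs))
    kn = prior.kappa + n
    nun = prior.nu + n
    mun = (prior.kappa * prior.mu + n * xbar) / kn
    ss = float(np.sum((xs - xbar) ** 2))
    nun_s2 = (
        prior.nu * prior.sigma2
        + ss
        + (prior.kappa * n / kn) * (xbar - prior.mu) ** 2
    )
    return NixBelief(mun, kn, nun_s2 / nun, nun, prior.n + n)


@dataclass(frozen=True)
class PredictivePmf:
    """Posterior predictive discretised onto a value grid spanning [1, 100].

    Probability mass outside the rating scale is folded back in by
    renormalisation; ``probs`` sums to 1.
    """

    grid: np.ndarray
    probs: np.ndarray

    def p_exceed(self, value: float) -> float:
        """Probability that a future draw strictly exceeds ``value``."""
        return float(self.probs[self.grid > value].sum())

    def p_exceed_grid(self) -> np.ndarray:
        """p_exceed evaluated at every grid point (strict, vectorised)."""
        tail = np.cumsum(self.probs[::-1])[::-1]
        return np.concatenate([tail[1:], [0.0]])

    def mean(self) -> float:
        return float(self.grid @ self.probs)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.grid, size=size, p=self.probs)


def value_grid(grid_size: int = DEFAULT_GRID_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin edges and centres spanning the 1-100 scale."""
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    edges = np.linspace(VALUE_MIN, VALUE_MAX, grid_size + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return edges, centres


def predictive_pmf(belief: NixBelief, grid_size: int = DEFAULT_GRID_SIZE) -> PredictivePmf:
    """Discretised Student-t posterior predictive over the value grid."""
    edges, centres = value_grid(grid_size)
    df, loc, scale = belief.predictive_params
    cdf = stats.t.cdf(edges, df=df, loc=loc, scale=scale)
    probs = np.diff(cdf)
    total = probs.sum()
    if total <= 0:  # pathological prior far off-scale; fall back to uniform
        probs = np.full(grid_size, 1.0 / grid_size)
    else:
        probs = probs / total
    return PredictivePmf(grid=centres, probs=probs)
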
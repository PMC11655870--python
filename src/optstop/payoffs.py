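"""Payoff schemes: how a choice's final rank (or value) maps to reward.

Three schemes from the smartphone-price studies:

* ``continuous`` - reward commensurate with the chosen option's own value
  (the classic Gilbert-Mosteller formulation);
* ``top3_money`` - 12p / 8p / 4p / 0 for the best, second-best, third-best
  and any other final rank;
* ``top3_stars`` - 5 / 3 / 1 / 0 stars for the same ranks.

All payoffs are rescaled to [0, 1] so that fitted parameters (notably the
cost-to-sample C) share a scale across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .task import VALUE_MAX, VALUE_MIN

CONTINUOUS = "continuous"
TOP3_MONEY = "top3_money"
TOP3_STARS = "top3_stars"


@dataclass(frozen=True)
class PayoffScheme:
    """Reward function R over final ranks (or option values).

    ``rank_rewards`` holds the raw rewards for ranks 1, 2, ... in their native
    units; they are normalised to [0, 1] when evaluated.  For the continuous
    scheme the option's own value is rescaled instead and ranks are ignored.
    """

    kind: str
    rank_rewards: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, TOP3_MONEY, TOP3_STARS):
            raise ValueError(f"unknown payoff scheme {self.kind!r}")
        if self.kind != CONTINUOUS:
            r = self.rank_rewards
            if not r or any(a < b for a, b in zip(r, r[1:])):
                raise ValueError("rank rewards must be non-increasing in rank")

    @classmethod
    def continuous(cls) -> "PayoffScheme":
        return cls(CONTINUOUS)

    @classmethod
    def top3_money(cls) -> "PayoffScheme":
        return cls(TOP3_MONEY, (0.12, 0.08, 0.04))

    @classmethod
    def top3_stars(cls) -> "PayoffScheme":
        return cls(TOP3_STARS, (5.0, 3.0, 1.0))

    @classmethod
    def from_kind(cls, kind: str) -> "PayoffScheme":
        return {
            CONTINUOUS: cls.continuous,
            TOP3_MONEY: cls.top3_money,
            TOP3_STARS: cls.top3_stars,
        }[kind]()

    @property
    def is_rank_based(self) -> bool:
        return self.kind != CONTINUOUS

    def scaled_rank_rewards(self, n_options: int) -> np.ndarray:
        """Rewards for final ranks 1..N, normalised so the best rank pays 1."""
        if not self.is_rank_based:
            raise ValueError("continuous scheme has no rank rewards")
        rewards = np.zeros(n_options)
        raw = np.asarray(self.rank_rewards, dtype=float)
        k = min(raw.size, n_options)
        rewards[:k] = raw[:k] / raw.max()
        return rewards

    def value_reward(self, value) -> np.ndarray | float:
        """Continuous payoff: option value rescaled from [1, 100] to [0, 1]."""
        if self.is_rank_based:
            raise ValueError("rank-based scheme rewards ranks, not raw values")
        return (np.asarray(value, dtype=float) - VALUE_MIN) / (VALUE_MAX - VALUE_MIN)


def rank_outcome_distribution(h: int, t: int, n_options: int, p_exceed: float):
    """Distribution of the final rank of the current option if taken now.

    ``h`` of the t options seen so far outrank nothing worse than the current
    one; each of the N-t future draws independently exceeds the current value
    with probability ``p_exceed``, so the final rank is h + K with
    K ~ Binomial(N - t, p_exceed).

    Returns (ranks, probs) arrays for ranks h..h+(N-t).
    """
    if not 1 <= h <= t <= n_options:
        raise ValueError("need 1 <= h <= t <= n_options")
    if not 0.0 <= p_exceed <= 1.0:
        raise ValueError("p_exceed must be a probability")
    m = n_options - t
    ks = np.arange(m + 1)
    probs = np.array(
        [comb(m, k) * p_exceed**k * (1 - p_exceed) ** (m - k) for k in ks]
    )
    return h + ks, probs


def expected_rank_reward(
    h: int, t: int, n_options: int, p_exceed: float, rewards: np.ndarray
) -> float:
    """E[R(final rank)] for taking now under a rank-based scheme.

    Only the ranks with non-zero reward contribute, so the binomial sum is
    truncated accordingly.
    """
    m = n_options - t
    nonzero = np.nonzero(rewards)[0]
    if nonzero.size == 0:
        return 0.0
    k_max = min(m, int(nonzero.max()) - (h - 1))
    total = 0.0
    for k in range(0, k_max + 1):
        rank = h + k  # 1-based final rank
        if rank > n_options:
            break
        total += (
            comb(m, k)
            * p_exceed**k
            * (1 - p_exceed) ** (m - k)
            * rewards[rank - 1]
        )
    return float(total)
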
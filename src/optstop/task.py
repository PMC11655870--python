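"""Task data model for sequential price search (optimal stopping).

Participants (or simulated agents) view a fixed-length sequence of option
values one at a time and, at each position, either *take* the current option
(ending the search) or *sample* the next one.  Option values live on a common
1-100 attractiveness scale, where 100 is the best option: objective prices in
GBP are reflected around their mean and rescaled onto that range, while
subjective values are the average of two attractiveness ratings that were
already given on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALUE_MIN = 1.0
VALUE_MAX = 100.0

ACTION_TAKE = "take"
ACTION_SAMPLE = "sample"


class DegenerateScaleError(ValueError):
    """All prices identical: the reflect-and-rescale map is undefined."""


@dataclass(frozen=True)
class PriceSet:
    """A market of positive prices (GBP) from which option sequences are drawn."""

    prices: np.ndarray

    def __post_init__(self) -> None:
        prices = np.asarray(self.prices, dtype=float)
        object.__setattr__(self, "prices", prices)
        if prices.ndim != 1 or prices.size < 2:
            raise ValueError("a price set needs at least two prices")
        if np.any(prices <= 0):
            raise ValueError("prices must be positive currency amounts")
        if np.ptp(prices) == 0:
            raise DegenerateScaleError("all prices are equal; rescaling undefined")

    @property
    def n(self) -> int:
        return int(self.prices.size)


@dataclass(frozen=True)
class OptionSequence:
    """An ordered, fixed-length list of option values on the 1-100 scale."""

    values: np.ndarray
    value_kind: str = "objective"  # objective | subjective

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("an option sequence needs at least two options")
        if np.any(values < VALUE_MIN) or np.any(values > VALUE_MAX):
            raise ValueError("option values must lie on the 1-100 scale")
        if self.value_kind not in ("objective", "subjective"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n_options(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DecisionContext:
    """One decision point: position ``t`` (1-based) inside an ``n_options``-long
    sequence, the observed prefix (which includes the current option as its last
    element), the current value and its relative rank ``h`` (1 = best so far)."""

    t: int
    n_options: int
    prefix: np.ndarray
    value: float
    h: int

    @classmethod
    def from_prefix(cls, prefix, n_options: int) -> "DecisionContext":
        prefix = np.asarray(prefix, dtype=float)
        t = int(prefix.size)
        if not 1 <= t <= n_options:
            raise ValueError("prefix length must be between 1 and n_options")
        return cls(
            t=t,
            n_options=int(n_options),
            prefix=prefix,
            value=float(prefix[-1]),
            h=relative_rank(prefix),
        )


@dataclass(frozen=True)
class ChoiceRecord:
    """One viewed option: the action taken at that position.

    ``forced`` is true only for the default take at the final position, where
    no free decision exists.
    """

    participant_id: str
    condition: str
    sequence_id: int
    position: int
    action: str
    forced: bool = False

    def __post_init__(self) -> None:
        if self.action not in (ACTION_TAKE, ACTION_SAMPLE):
            raise ValueError(f"invalid action {self.action!r}")
        if self.forced and self.action != ACTION_TAKE:
            raise ValueError("only a take can be forced")


@dataclass
class ParticipantData:
    """All sequences and stopping decisions for one (real or simulated) participant.

    ``prior_values`` are the values used to initialise the agent's belief about
    the generating distribution (the rescaled market for objective-value runs,
    the participant's averaged ratings for subjective-value runs).
    """

    participant_id: str
    sequences: list = field(default_factory=list)  # list of 1-100 value arrays
    stops: list = field(default_factory=list)  # 1-based stop positions
    forced: list = field(default_factory=list)  # per-sequence forced-take flags
    prior_values: np.ndarray | None = None
    value_kind: str = "objective"
    condition: str = "default"
    n_options: int = 0  # 0: infer from the first sequence

    def __post_init__(self) -> None:
        if self.n_options == 0 and self.sequences:
            self.n_options = int(len(self.sequences[0]))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def mean_samples(self) -> float:
        """Mean number of samples before decision (the study's main DV)."""
        return float(np.mean(self.stops))

    @property
    def n_free_decisions(self) -> int:
        """Decisions with two available actions.

        Positions before the stop are free 'sample' choices; the take itself
        is free only before the final position, where taking is the only
        available action.
        """
        n = self.n_options
        total = 0
        for stop, was_forced in zip(self.stops, self.forced):
            if was_forced or stop >= n:
                total += min(stop, n) - 1
            else:
                total += stop
        return total


def reflect_rescale(prices) -> np.ndarray:
    """Map prices to the 1-100 attractiveness scale, reversing the order.

    The composition of a reflection about the mean and an affine rescale: the
    highest (worst) price maps to 1 and the lowest (best) price to 100, so all
    models solve a maximisation problem on a common scale.
    """
    if isinstance(prices, PriceSet):
        prices = prices.prices
    prices = np.asarray(prices, dtype=float)
    if prices.size < 2:
        raise ValueError("need at least two prices")
    span = prices.max() - prices.min()
    if span == 0:
        raise DegenerateScaleError("all prices are equal; rescaling undefined")
    return VALUE_MIN + (VALUE_MAX - VALUE_MIN) * (prices.max() - prices) / span


def subjective_values(ratings_pass1, ratings_pass2) -> np.ndarray:
    """Average two attractiveness-rating passes into subjective values."""
    r1 = np.asarray(ratings_pass1, dtype=float)
    r2 = np.asarray(ratings_pass2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("rating passes must have equal length")
    for r in (r1, r2):
        if np.any(r < VALUE_MIN) or np.any(r > VALUE_MAX):
            raise ValueError("ratings must lie on the 1-100 scale")
    return (r1 + r2) / 2.0


def relative_rank(prefix) -> int:
    """Relative rank h of the current (last) option among those seen so far.

    h = 1 + number of strictly greater earlier values; ties share the better
    rank, so the first option always has h = 1.
    """
    prefix = np.asarray(prefix, dtype=float)
    if prefix.size == 0:
        raise ValueError("empty prefix")
    return int(1 + np.sum(prefix[:-1] > prefix[-1]))


def relative_ranks(values) -> np.ndarray:
    """Relative rank at every position of a sequence (vectorised helper)."""
    values = np.asarray(values, dtype=float)
    return np.array(
        [1 + int(np.sum(values[:t] > values[t])) for t in range(values.size)],
        dtype=int,
    )


def samples_to_decision(records) -> int:
    """Number of samples before decision for one sequence of choice records.

    The position of the take action; a forced take at the final position counts
    as the full sequence length (the participant viewed every option).
    """
    takes = [r for r in records if r.action == ACTION_TAKE]
    if len(takes) != 1:
        raise ValueError(f"expected exactly one take per sequence, got {len(takes)}")
    return int(takes[0].position)


def final_rank(values, stop_position: int) -> int:
    """Rank of the chosen option among all options in the sequence.

    1 = best (highest value on the 1-100 scale); tied values share the better
    rank.
    """
    values = np.asarray(values, dtype=float)
    if not 1 <= stop_position <= values.size:
        raise ValueError("stop position outside the sequence")
    chosen = values[stop_position - 1]
    return int(1 + np.sum(values > chosen))
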
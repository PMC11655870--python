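"""Synthetic study-condition generator.

Emulates the inputs the analysis pipeline assumes: a market of 90 smartphone
contract prices (GBP), two attractiveness-rating passes per price with a
target test-retest correlation, fixed-length option sequences drawn without
replacement from the market, and simulated agent cohorts with a ground-truth
parameter ledger.  Every artefact is a pure function of its seed and
configuration.

The published 90-price list is not reproduced here; the default market is a
normal(900, 150) GBP distribution truncated below 300 - a plausible stand-in
for 2-year flagship contracts - and the family is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .agents import AgentSpec, simulate_stop_positions
from .beliefs import DEFAULT_GRID_SIZE
from .payoffs import PayoffScheme
from .task import (
    VALUE_MAX,
    VALUE_MIN,
    ParticipantData,
    PriceSet,
    reflect_rescale,
    subjective_values,
)


@dataclass(frozen=True)
class MarketConfig:
    """Price-market stand-in: truncated normal on GBP."""

    n_prices: int = 90
    mean: float = 900.0
    sd: float = 150.0
    minimum: float = 300.0

    def __post_init__(self) -> None:
        if self.n_prices < 2:
            raise ValueError("a market needs at least two prices")
        if self.sd <= 0:
            raise ValueError("price scale must be positive")


@dataclass(frozen=True)
class RatingModel:
    """Two-pass rating noise model with a target test-retest Pearson r.

    Ratings are the underlying scaled value plus i.i.d. Gaussian noise,
    clipped to the 1-100 scale.  The noise variance follows the attenuation
    formula sigma_e^2 = Var(values) * (1 - r) / r, which makes the expected
    between-pass correlation equal r (ignoring clipping).
    """

    target_r: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r < 1.0:
            raise ValueError("target test-retest r must lie in (0, 1)")

    def noise_variance(self, values) -> float:
        var = float(np.var(np.asarray(values, dtype=float), ddof=1))
        return var * (1.0 - self.target_r) / self.target_r


@dataclass(frozen=True)
class CohortDesign:
    """A simulated study condition.

    Defaults mirror the fully randomised 12-option design: six sequences of
    12 options per participant, drawn without replacement from the 90-price
    market, continuous payoff.  ``model_mix`` lists (model, theta, beta)
    entries cycled over participants; theta may be a constant or a callable
    drawing from a parameter distribution given an rng.
    """

    n_participants: int = 50
    n_sequences: int = 6
    n_options: int = 12
    scheme: PayoffScheme = field(default_factory=PayoffScheme.continuous)
    model_mix: tuple = (("ideal", None, 10.0),)
    value_kind: str = "objective"
    market: MarketConfig = field(default_factory=MarketConfig)
    rating_model: RatingModel = field(default_factory=RatingModel)
    fixed_sequences: bool = False
    grid_size: int = DEFAULT_GRID_SIZE
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_options > self.market.n_prices:
            raise ValueError("sequence length exceeds the market size")
        if self.n_options < 2:
            raise ValueError("sequences need at least two options")
        if not self.model_mix:
            raise ValueError("empty model mix")


def _rng(master_seed: int, stream: int) -> np.random.Generator:
    """Counter-derived generator: each stream is independent of the others."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(stream,)))


_STREAM_MARKET = 0
_STREAM_RATINGS = 1
_STREAM_SEQUENCES = 2
_STREAM_PARAMS = 3
_STREAM_CHOICES = 4


def generate_market(config: MarketConfig, rng: np.random.Generator) -> PriceSet:
    """Seeded draw of the price market from the configured family."""
    a = (config.minimum - config.mean) / config.sd
    prices = stats.truncnorm.rvs(
        a, np.inf, loc=config.mean, scale=config.sd,
        size=config.n_prices, random_state=rng,
    )
    return PriceSet(prices=prices)


def generate_ratings(
    scaled_values, model: RatingModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two rating passes over the scaled values, clipped to the 1-100 scale."""
    values = np.asarray(scaled_values, dtype=float)
    sd = np.sqrt(model.noise_variance(values))
    passes = []
    for _ in range(2):
        noisy = values + rng.normal(0.0, sd, size=values.shape)
        passes.append(np.clip(noisy, VALUE_MIN, VALUE_MAX))
    return passes[0], passes[1]


def build_sequences(
    scaled_values, design: CohortDesign, rng: np.random.Generator
) -> list[np.ndarray]:
    """Option sequences for one participant: N values without replacement each."""
    values = np.asarray(scaled_values, dtype=float)
    if design.n_options > values.size:
        raise ValueError("sequence length exceeds the value pool")
    return [
        values[rng.choice(values.size, size=design.n_options, replace=False)]
        for _ in range(design.n_sequences)
    ]


def _draw_theta(theta, rng: np.random.Generator):
    return theta(rng) if callable(theta) else theta


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Simulate a full cohort; returns participants plus a ground-truth ledger.

    The market is drawn once; each participant gets its own sequences (or the
    shared fixed set when ``fixed_sequences`` is on, mirroring designs where
    option values were fixed in advance and only sequence order randomised),
    its own ratings when the cohort uses subjective values, and softmax
    choices from its assigned agent.  Fully reproducible from the master seed.
    """
    market = generate_market(design.market, _rng(design.master_seed, _STREAM_MARKET))
    objective_values = reflect_rescale(market)

    seq_rng = _rng(design.master_seed, _STREAM_SEQUENCES)
    fixed = (
        build_sequences(objective_values, design, seq_rng)
        if design.fixed_sequences
        else None
    )
    rating_rng = _rng(design.master_seed, _STREAM_RATINGS)
    param_rng = _rng(design.master_seed, _STREAM_PARAMS)
    choice_rng = _rng(design.master_seed, _STREAM_CHOICES)

    participants: list[ParticipantData] = []
    truth_rows = []
    for p in range(design.n_participants):
        model, theta, beta = design.model_mix[p % len(design.model_mix)]
        theta_val = _draw_theta(theta, param_rng)
        spec = AgentSpec(
            model=model, theta=theta_val, beta=float(beta),
            value_kind=design.value_kind,
        )
        spec.validate_for_length(design.n_options)

        if design.value_kind == "subjective":
            pass1, pass2 = generate_ratings(
                objective_values, design.rating_model, rating_rng
            )
            pool = subjective_values(pass1, pass2)
        else:
            pool = objective_values
        if design.fixed_sequences:
            # fixed option values; only the sequence order varies by participant
            order = seq_rng.permutation(len(fixed))
            sequences = [fixed[i] for i in order]
        else:
            sequences = build_sequences(pool, design, seq_rng)

        stops = simulate_stop_positions(
            spec, sequences, pool, design.scheme,
            mode="softmax", rng=choice_rng, grid_size=design.grid_size,
        )
        pid = f"sim{p:03d}"
        participants.append(
            ParticipantData(
                participant_id=pid,
                sequences=sequences,
                stops=[int(s) for s in stops],
                forced=[int(s) == design.n_options for s in stops],
                prior_values=pool,
                value_kind=design.value_kind,
                condition=f"{design.scheme.kind}_N{design.n_options}",
            )
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "model": model,
                "theta": np.nan if theta_val is None else float(theta_val),
                "beta": float(beta),
                "value_kind": design.value_kind,
                "seed": design.master_seed,
            }
        )
    return participants, pd.DataFrame(truth_rows)


def choices_frame(participants: list[ParticipantData]) -> pd.DataFrame:
    """Flatten participants into the one-row-per-viewed-option choices table."""
    rows = []
    for p in participants:
        for s, (values, stop, forced_) in enumerate(
            zip(p.sequences, p.stops, p.forced)
        ):
            for pos in range(1, stop + 1):
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "condition": p.condition,
                        "sequence_id": s,
                        "position": pos,
                        "n_options": p.n_options,
                        "option_value": float(values[pos - 1]),
                        "action": "take" if pos == stop else "sample",
                        "forced": int(pos == stop and forced_),
                    }
                )
    return pd.DataFrame(rows)
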
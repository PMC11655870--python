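"""Dataset IO, configuration and end-to-end pipeline orchestration.

Choice data round-trips through a flat CSV (one row per viewed option):
participant_id, condition, sequence_id, position, option_value, action
(take | sample), forced (0/1), plus an n_options column recording the
sequence horizon (the file holds only viewed options, so the horizon is not
otherwise recoverable when a participant stopped early; if the column is
absent the horizon is inferred as the largest observed position in the
dataset).  Ratings use participant_id, price_gbp, pass (1/2), rating.

``run_pipeline`` executes simulate -> fit -> compare (or recover) from a
config mapping, writes CSV outputs plus a manifest recording the config
hash, seed and package version, and derives every stage's random stream
from the master seed by a counter so adding a stage never perturbs earlier
ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import best_fit_counts, compare_models
from .fitting import FitConfig, fit_cohort
from .payoffs import PayoffScheme
from .recovery import model_recovery, parameter_recovery
from .synthetic import CohortDesign, MarketConfig, RatingModel, choices_frame, simulate_cohort
from .task import VALUE_MAX, VALUE_MIN, ParticipantData

logger = logging.getLogger("optstop")

REQUIRED_CHOICE_COLUMNS = (
    "participant_id",
    "condition",
    "sequence_id",
    "position",
    "option_value",
    "action",
    "forced",
)


class SchemaError(ValueError):
    """A dataset violates the choices/ratings schema; names offending rows."""


def _fail(row_index, message: str) -> None:
    raise SchemaError(f"row {row_index}: {message}")


def load_dataset(
    choices_path,
    ratings_path=None,
    value_kind: str = "objective",
) -> list[ParticipantData]:
    """Read and validate a choices CSV (plus optional ratings CSV).

    For objective-value runs the prior-generating values are the distinct
    option values observed across the dataset; for subjective runs each
    participant's averaged ratings are used instead.
    """
    df = pd.read_csv(choices_path)
    missing = [c for c in REQUIRED_CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"choices CSV missing columns: {missing}")
    bad_action = df.index[~df["action"].isin(["take", "sample"])]
    if len(bad_action):
        _fail(int(bad_action[0]), f"invalid action {df.loc[bad_action[0], 'action']!r}")
    out_of_scale = df.index[
        (df["option_value"] < VALUE_MIN) | (df["option_value"] > VALUE_MAX)
    ]
    if len(out_of_scale):
        _fail(int(out_of_scale[0]), "option_value outside the 1-100 scale")

    ratings = None
    if ratings_path is not None:
        ratings = pd.read_csv(ratings_path)
        for col in ("participant_id", "price_gbp", "pass", "rating"):
            if col not in ratings.columns:
                raise SchemaError(f"ratings CSV missing column {col!r}")

    horizon_fallback = int(df["position"].max())
    pool_objective = np.unique(df["option_value"].to_numpy(dtype=float))

    participants = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        sequences, stops, forced = [], [], []
        n_options = (
            int(pdf["n_options"].iloc[0]) if "n_options" in pdf else horizon_fallback
        )
        for sid, sdf in pdf.groupby("sequence_id", sort=True):
            sdf = sdf.sort_values("position")
            takes = sdf.index[sdf["action"] == "take"]
            if len(takes) != 1:
                _fail(
                    int(sdf.index[0]),
                    f"sequence {sid} of participant {pid} has {len(takes)} takes",
                )
            take_row = sdf.loc[takes[0]]
            stop = int(take_row["position"])
            if int(take_row["position"]) != int(sdf["position"].max()):
                _fail(int(takes[0]), "take is not the last viewed position")
            if bool(take_row["forced"]) and stop != n_options:
                _fail(int(takes[0]), "forced take before the final position")
            sequences.append(sdf["option_value"].to_numpy(dtype=float))
            stops.append(stop)
            forced.append(bool(take_row["forced"]))

        if value_kind == "subjective":
            if ratings is None:
                raise SchemaError("subjective value_kind requires a ratings CSV")
            rdf = ratings[ratings["participant_id"] == pid]
            p1 = rdf[rdf["pass"] == 1].sort_values("price_gbp")["rating"].to_numpy()
            p2 = rdf[rdf["pass"] == 2].sort_values("price_gbp")["rating"].to_numpy()
            if p1.size == 0 or p1.size != p2.size:
                raise SchemaError(f"participant {pid}: malformed rating passes")
            prior_values = (p1 + p2) / 2.0
        else:
            prior_values = pool_objective

        participants.append(
            ParticipantData(
                participant_id=str(pid),
                sequences=sequences,
                stops=stops,
                forced=forced,
                prior_values=prior_values,
                value_kind=value_kind,
                condition=str(pdf["condition"].iloc[0]),
                n_options=n_options,
            )
        )
    return participants


def write_dataset(participants, choices_path) -> None:
    choices_frame(participants).to_csv(choices_path, index=False)


# ---------------------------------------------------------------------------
# configuration


def design_from_config(cfg: dict, master_seed: int) -> CohortDesign:
    synth = dict(cfg.get("synthetic", {}))
    market = MarketConfig(**synth.pop("market", {}))
    rating = RatingModel(**synth.pop("ratings", {}))
    scheme = PayoffScheme.from_kind(synth.pop("scheme", "continuous"))
    mix = tuple(
        (m["model"], m.get("theta"), m.get("beta", 10.0))
        for m in synth.pop("model_mix", [{"model": "ideal", "beta": 10.0}])
    )
    return CohortDesign(
        market=market,
        rating_model=rating,
        scheme=scheme,
        model_mix=mix,
        master_seed=master_seed,
        **synth,
    )


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Execute the configured stages; returns a manifest of written outputs.

    Stages (as requested by ``config['stages']``, default simulate+fit+compare):
    simulate a cohort, fit the bias models per participant, compare models
    (pairwise mean-BIC tests and best-fit counts), or run recovery suites.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate", "fit", "compare"])
    manifest = {
        "seed": int(seed),
        "config_hash": _config_hash(config),
        "config": json.loads(json.dumps(config, default=str)),
        "version": __version__,
        "stages": list(stages),
        "outputs": {},
    }

    participants = None
    design = design_from_config(config, master_seed=seed)
    fits = None
    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                participants, truth = simulate_cohort(design)
                write_dataset(participants, out / "choices.csv")
                truth.to_csv(out / "ground_truth.csv", index=False)
                manifest["outputs"]["choices"] = "choices.csv"
                manifest["outputs"]["ground_truth"] = "ground_truth.csv"
            elif stage == "fit":
                if participants is None:
                    participants = load_dataset(
                        config["data"]["choices"],
                        config.get("data", {}).get("ratings"),
                        value_kind=config.get("data", {}).get("value_kind", "objective"),
                    )
                fit_cfg = FitConfig(
                    scheme=design.scheme,
                    grid_size=design.grid_size,
                    **config.get("fitting", {}),
                )
                fits = fit_cohort(participants, config=fit_cfg)
                fits.to_csv(out / "fits.csv", index=False)
                manifest["outputs"]["fits"] = "fits.csv"
            elif stage == "compare":
                if fits is None:
                    raise RuntimeError("compare stage needs fits")
                table = compare_models(fits)
                table.to_csv(out / "comparison.csv", index=False)
                pivot = fits.pivot(
                    index="participant_id", columns="model", values="bic"
                )
                counts = best_fit_counts(pivot)
                counts.rename("n_best_fit").to_csv(out / "best_fit_counts.csv")
                manifest["outputs"]["comparison"] = "comparison.csv"
                manifest["outputs"]["best_fit_counts"] = "best_fit_counts.csv"
            elif stage == "recover":
                rec_cfg = config.get("recovery", {})
                kind = rec_cfg.get("kind", "model")
                if kind == "parameter":
                    result = parameter_recovery(
                        rec_cfg.get("model", "biased_prior"),
                        beta=rec_cfg.get("beta", 10.0),
                        design=design,
                        seed=seed,
                    )
                    result.table.to_csv(out / "parameter_recovery.csv", index=False)
                    manifest["outputs"]["parameter_recovery"] = "parameter_recovery.csv"
                    manifest["parameter_r"] = result.parameter_r
                else:
                    confusion = model_recovery(
                        design=design,
                        n_simulants=rec_cfg.get("n_simulants", 20),
                        beta=rec_cfg.get("beta", 10.0),
                        seed=seed,
                    )
                    confusion.to_csv(out / "model_confusion.csv")
                    manifest["outputs"]["model_confusion"] = "model_confusion.csv"
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception:
            logger.error("stage %s failed", stage)
            raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
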
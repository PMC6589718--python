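"""Experiment drivers: run the threshold and rating designs on a synthetic cohort.

Three threshold designs are provided as presets.  All use 2IFC blocks driven
by the 3-down/1-up staircase:

* experiment ``1`` — 2 C/s ramps, 6-s stimuli with a 1-s initial hold, both
  changes start from 45 C; detection then discrimination blocks, for both a
  radiant and a contact modality (the modality is a label only).
* experiment ``2`` — 4 C/s ramps, 6-s stimuli with a 3-s hold, detection only,
  radiant only; plus a separate pain-rating task (four 46/47 C profiles,
  14 repetitions each in seeded random order, two 28-trial blocks).
* experiment ``3`` — 4 C/s ramps, 10-s stimuli with a 5-s hold; decreases
  start from 47 C while increases start from 45 C, putting the two staircases
  in overlapping temperature ranges; 4-point confidence scale.

Direction order is counterbalanced by participant parity, and detection
always precedes the matching discrimination block so its estimate can serve
as the discrimination reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import block_rng
from .observer import ObserverSpec, simulate_rating
from .staircase import (
    BlockLog,
    StaircaseConfig,
    estimate_threshold,
    run_block,
)
from .stimuli import InvalidDesignError, ProfileSpec, build_profile

ExperimentId = Literal["1", "2", "3", "rating"]

RATING_REPEATS = 14
RATING_BLOCK_SIZE = 28


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters for one experiment run."""

    experiment_id: str
    ramp_rate: float
    stimulus_duration: float
    initial_hold: float
    base_increase: float = 45.0
    base_decrease: float = 45.0
    confidence_scale: str = "binary"
    initial_delta: float = 2.5
    tasks: tuple[str, ...] = ("detection",)
    modalities: tuple[str, ...] = ("radiant",)
    n_trials: int = 30
    n_discard: int = 10
    # rating-task parameters (experiment "rating" / experiment 2's second task)
    rating_temps: tuple[float, float] = (46.0, 47.0)
    rating_repeats: int = RATING_REPEATS
    rating_block_size: int = RATING_BLOCK_SIZE

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ExperimentConfig":
        d = json.loads(payload)
        for key in ("tasks", "modalities", "rating_temps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_PRESETS: dict[str, dict] = {
    "1": dict(
        experiment_id="1",
        ramp_rate=2.0,
        stimulus_duration=6.0,
        initial_hold=1.0,
        base_increase=45.0,
        base_decrease=45.0,
        confidence_scale="binary",
        tasks=("detection", "discrimination"),
        modalities=("radiant", "contact"),
    ),
    "2": dict(
        experiment_id="2",
        ramp_rate=4.0,
        stimulus_duration=6.0,
        initial_hold=3.0,
        base_increase=45.0,
        base_decrease=45.0,
        confidence_scale="binary",
        tasks=("detection",),
        modalities=("radiant",),
    ),
    "3": dict(
        experiment_id="3",
        ramp_rate=4.0,
        stimulus_duration=10.0,
        initial_hold=5.0,
        base_increase=45.0,
        base_decrease=47.0,
        confidence_scale="four_point",
        tasks=("detection",),
        modalities=("radiant",),
    ),
    "rating": dict(
        experiment_id="rating",
        ramp_rate=4.0,
        stimulus_duration=6.0,
        initial_hold=3.0,
        base_increase=45.0,
        base_decrease=45.0,
        confidence_scale="binary",
        tasks=(),
        modalities=("radiant",),
    ),
}


def preset(experiment_id: str) -> ExperimentConfig:
    """Return the canonical configuration for one of the built-in designs."""
    try:
        return ExperimentConfig(**_PRESETS[str(experiment_id)])
    except KeyError:
        raise InvalidDesignError(
            f"unknown experiment preset {experiment_id!r}; "
            f"choose from {sorted(_PRESETS)}"
        ) from None


@dataclass
class CohortResult:
    """Per-participant threshold table plus the raw block logs behind it."""

    config: ExperimentConfig
    seed: int
    thresholds: pd.DataFrame  # participant_id, modality, task, direction,
    #                           threshold_c, bound_violation, excluded
    block_logs: list[tuple[str, BlockLog]] = field(default_factory=list)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        blocks = out / "blocks"
        blocks.mkdir(exist_ok=True)
        for block_id, log in self.block_logs:
            log.to_csv(blocks / f"{block_id}.csv")


def _direction_order(participant_index: int) -> tuple[str, str]:
    # counterbalance by parity: even-indexed participants run increases first
    if participant_index % 2 == 0:
        return ("increase", "decrease")
    return ("decrease", "increase")


def _staircase_config(
    config: ExperimentConfig,
    direction: str,
    mode: str,
    reference_delta: float | None = None,
    initial_delta: float | None = None,
) -> StaircaseConfig:
    base = config.base_increase if direction == "increase" else config.base_decrease
    return StaircaseConfig(
        base_temp=base,
        direction=direction,  # type: ignore[arg-type]
        mode=mode,  # type: ignore[arg-type]
        initial_delta=config.initial_delta if initial_delta is None else initial_delta,
        n_trials=config.n_trials,
        n_discard=config.n_discard,
        reference_delta=reference_delta,
        ramp_rate=config.ramp_rate,
        initial_hold=config.initial_hold,
        stimulus_duration=config.stimulus_duration,
        confidence_scale=config.confidence_scale,  # type: ignore[arg-type]
    )


def run_experiment(
    config: ExperimentConfig,
    cohort: Sequence[ObserverSpec],
    seed: int,
    progress=None,
) -> CohortResult:
    """Run all threshold blocks of one design on every cohort member.

    Deterministic in ``seed``: each (participant, block) pair draws from its
    own RNG substream, so results for one participant are unaffected by the
    presence of others.  Participants whose discrimination staircase pinned at
    a temperature bound are flagged ``excluded`` on their discrimination rows,
    mirroring post-hoc exclusion; detection rows are never excluded.
    """
    if len(cohort) == 0:
        raise InvalidDesignError("cohort is empty")
    if "detection" not in config.tasks:
        raise InvalidDesignError(f"{config.experiment_id!r} is not a threshold design")
    rows = []
    block_logs: list[tuple[str, BlockLog]] = []
    for pid, obs in enumerate(cohort):
        block_index = 0
        for modality in config.modalities:
            detection_refs: dict[str, float] = {}
            disc_violated = False
            pending = []
            for direction in _direction_order(pid):
                sc = _staircase_config(config, direction, "detection")
                rng = block_rng(seed, pid, block_index)
                block_index += 1
                log = run_block(sc, obs, rng)
                block_id = f"p{pid:02d}_{modality}_detection_{direction}"
                est = estimate_threshold(log, sc, block_id=block_id)
                detection_refs[direction] = est.value
                block_logs.append((block_id, log))
                rows.append(
                    dict(
                        participant_id=pid,
                        modality=modality,
                        task="detection",
                        direction=direction,
                        threshold_c=est.value,
                        bound_violation=est.bound_violation,
                        excluded=False,
                    )
                )
                if "discrimination" in config.tasks:
                    ref = est.value
                    sc_d = _staircase_config(
                        config,
                        direction,
                        "discrimination",
                        reference_delta=ref,
                        initial_delta=ref + config.initial_delta,
                    )
                    rng = block_rng(seed, pid, block_index)
                    block_index += 1
                    log_d = run_block(sc_d, obs, rng)
                    block_id_d = f"p{pid:02d}_{modality}_discrimination_{direction}"
                    est_d = estimate_threshold(log_d, sc_d, block_id=block_id_d)
                    disc_violated = disc_violated or est_d.bound_violation
                    block_logs.append((block_id_d, log_d))
                    pending.append(
                        dict(
                            participant_id=pid,
                            modality=modality,
                            task="discrimination",
                            direction=direction,
                            threshold_c=est_d.value,
                            bound_violation=est_d.bound_violation,
                            excluded=False,
                        )
                    )
            for row in pending:
                row["excluded"] = disc_violated
                rows.append(row)
        if progress is not None:
            progress(pid, len(cohort))
    thresholds = pd.DataFrame(rows).sort_values(
        ["participant_id", "modality", "task", "direction"], kind="stable"
    )
    thresholds = thresholds.reset_index(drop=True)
    return CohortResult(
        config=config, seed=seed, thresholds=thresholds, block_logs=block_logs
    )


# ---------------------------------------------------------------------------
# Rating task (experiment 2, second session half)
# ---------------------------------------------------------------------------


def rating_profiles(config: ExperimentConfig) -> dict[str, ProfileSpec]:
    """The four rating-task stimulus types, keyed by ``start-end`` label."""
    low, high = config.rating_temps
    hold = config.initial_hold
    rate = config.ramp_rate
    dur = config.stimulus_duration
    return {
        f"{low:g}-{low:g}": ProfileSpec(low, hold, 0.0, rate, dur),
        f"{high:g}-{high:g}": ProfileSpec(high, hold, 0.0, rate, dur),
        f"{low:g}-{high:g}": ProfileSpec(low, hold, high - low, rate, dur),
        f"{high:g}-{low:g}": ProfileSpec(high, hold, low - high, rate, dur),
    }


def rating_schedule(
    config: ExperimentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Seeded random trial order: each profile type repeated, split in blocks."""
    labels = list(rating_profiles(config))
    order = np.repeat(np.arange(len(labels)), config.rating_repeats)
    rng.shuffle(order)
    n = len(order)
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "block": 1 + np.arange(n) // config.rating_block_size,
            "profile": [labels[i] for i in order],
        }
    )


def run_rating_task(
    config: ExperimentConfig,
    cohort: Sequence[ObserverSpec],
    seed: int,
) -> pd.DataFrame:
    """Simulate the pain-intensity rating task for the whole cohort.

    Returns one row per trial: participant_id, trial, block, profile,
    profile_kind (constant/variable), final_temp_c, rating.  The probe is 1 s
    before stimulus end, after the final temperature has been reached.
    """
    if len(cohort) == 0:
        raise InvalidDesignError("cohort is empty")
    specs = rating_profiles(config)
    profiles = {label: build_profile(spec) for label, spec in specs.items()}
    probe_time = config.stimulus_duration - 1.0
    frames = []
    for pid, obs in enumerate(cohort):
        rng = block_rng(seed, pid, 0, stream="rating")
        sched = rating_schedule(config, rng)
        ratings = [
            simulate_rating(profiles[label], probe_time, obs, rng)
            for label in sched["profile"]
        ]
        df = sched.copy()
        df.insert(0, "participant_id", pid)
        df["profile_kind"] = [
            "constant" if lbl.split("-")[0] == lbl.split("-")[1] else "variable"
            for lbl in df["profile"]
        ]
        df["final_temp_c"] = [specs[lbl].end_temp for lbl in df["profile"]]
        df["rating"] = ratings
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
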
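"""Transformed up-down (n-down/1-up) adaptive staircase and threshold estimator.

The default configuration is the 3-down/1-up rule with 0.5 C steps over
30-trial blocks: the tracked temperature change grows by one step after every
error and shrinks by one step after three successive correct responses, so
the procedure converges on the stimulus magnitude answered correctly with
probability 0.5**(1/3) ~ 79.4%.  The threshold estimate is the mean change
magnitude over the last 20 trials of a block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import observer as obs_mod
from .observer import Direction, ObserverSpec, TwoIntervalTrial, simulate_2ifc_trial
from .stimuli import (
    TEMP_CEILING,
    TEMP_FLOOR,
    InvalidDesignError,
    ProfileSpec,
    build_profile,
)

Mode = Literal["detection", "discrimination"]


class ThresholdUnattainableError(ValueError):
    """The target accuracy cannot be reached within the temperature bounds."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive block.

    ``reference_delta`` is only meaningful in discrimination mode, where it is
    the fixed smaller change (the participant's detection threshold) and the
    staircase adapts the larger change, kept strictly above the reference.
    """

    base_temp: float
    direction: Direction
    mode: Mode = "detection"
    n_down: int = 3
    n_up: int = 1
    step: float = 0.5
    initial_delta: float = 2.5
    n_trials: int = 30
    n_discard: int = 10
    ceiling: float = TEMP_CEILING
    floor: float = TEMP_FLOOR
    reference_delta: float | None = None
    # stimulus geometry for the trials this staircase drives
    ramp_rate: float = 2.0
    initial_hold: float = 1.0
    stimulus_duration: float = 6.0
    confidence_scale: Literal["binary", "four_point"] = "binary"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidDesignError("step must be positive")
        if self.n_down < 1 or self.n_up != 1:
            raise InvalidDesignError("rule must be n-down/1-up with n_down >= 1")
        if self.n_trials <= self.n_discard:
            raise InvalidDesignError("n_trials must exceed n_discard")
        if self.initial_delta < self.step:
            raise InvalidDesignError("initial_delta must be >= step")
        if self.mode == "discrimination":
            if self.reference_delta is None or self.reference_delta <= 0:
                raise InvalidDesignError(
                    "discrimination mode requires a positive reference_delta"
                )
        if not (self.floor <= self.base_temp <= self.ceiling):
            raise InvalidDesignError("base_temp outside [floor, ceiling]")

    @property
    def min_delta(self) -> float:
        """Smallest admissible adaptive delta (rule bound, not flagged)."""
        if self.mode == "discrimination":
            return self.reference_delta + self.step  # strictly above reference
        return self.step

    @property
    def max_delta(self) -> float:
        """Largest delta keeping the changing stimulus within bounds."""
        if self.direction == "increase":
            return self.ceiling - self.base_temp
        return self.base_temp - self.floor

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "StaircaseConfig":
        return cls(**json.loads(payload))


@dataclass(frozen=True)
class StaircaseState:
    trial_index: int = 0
    current_delta: float = 2.5
    consecutive_correct: int = 0
    history: tuple[tuple[float, bool, int], ...] = ()
    bound_violation: bool = False

    def __post_init__(self) -> None:
        if len(self.history) != self.trial_index:
            raise ValueError("history length must equal trial_index")


def initial_state(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_delta=config.initial_delta)


def staircase_update(
    state: StaircaseState,
    correct: bool,
    config: StaircaseConfig,
    confidence: int = 0,
) -> StaircaseState:
    """Apply one response to the staircase (Levitt transformed up-down rule).

    An incorrect answer raises the delta by one step and resets the run
    counter; the ``n_down``-th successive correct answer lowers it by one step
    and resets the counter.  The delta is clamped so the changing stimulus
    stays within [floor, ceiling]; clamping at the temperature bound sets
    ``bound_violation``.
    """
    if state.trial_index >= config.n_trials:
        raise InvalidDesignError("staircase update after block completion")
    delta = state.current_delta
    violated = state.bound_violation
    if correct:
        run = state.consecutive_correct + 1
        if run >= config.n_down:
            delta -= config.step
            run = 0
    else:
        run = 0
        delta += config.step
    if delta > config.max_delta:
        delta = config.max_delta
        violated = True
    if delta < config.min_delta:
        delta = config.min_delta
    return StaircaseState(
        trial_index=state.trial_index + 1,
        current_delta=delta,
        consecutive_correct=run,
        history=state.history + ((state.current_delta, bool(correct), confidence),),
        bound_violation=violated,
    )


# ---------------------------------------------------------------------------
# Block driver and logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    trial: int  # 1-based
    interval_of_change: int  # 1 or 2
    delta_c: float
    response_interval: int  # 1 or 2
    correct: bool
    confidence: int
    clamped: bool  # delta was pinned at the temperature bound on this trial


@dataclass
class BlockLog:
    config: StaircaseConfig
    records: list[TrialRecord] = field(default_factory=list)

    @property
    def bound_violation(self) -> bool:
        return any(r.clamped for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: StaircaseConfig | None = None) -> "BlockLog":
        df = pd.read_csv(path)
        records = [
            TrialRecord(
                trial=int(r.trial),
                interval_of_change=int(r.interval_of_change),
                delta_c=float(r.delta_c),
                response_interval=int(r.response_interval),
                correct=bool(r.correct),
                confidence=int(r.confidence),
                clamped=bool(r.clamped),
            )
            for r in df.itertuples()
        ]
        if config is None:
            config = StaircaseConfig(base_temp=45.0, direction="decrease")
        return cls(config=config, records=records)


@dataclass(frozen=True)
class ThresholdEstimate:
    value: float
    direction: Direction
    base_temp: float
    n_retained: int
    block_id: str = ""
    bound_violation: bool = False


def _effective_criteria(obs: ObserverSpec, scale: str) -> tuple[float, ...]:
    crit = obs.confidence_criteria
    if scale == "binary" and len(crit) > 1:
        return (crit[len(crit) // 2],)
    return crit


def _trial_profiles(
    config: StaircaseConfig, delta: float
) -> tuple[ProfileSpec, ProfileSpec]:
    """(standard, comparison) profile specs for the current delta."""
    sign = 1.0 if config.direction == "increase" else -1.0
    if config.mode == "detection":
        standard = ProfileSpec(
            config.base_temp, config.initial_hold, 0.0, config.ramp_rate,
            config.stimulus_duration,
        )
    else:
        standard = ProfileSpec(
            config.base_temp, config.initial_hold, sign * config.reference_delta,
            config.ramp_rate, config.stimulus_duration,
        )
    comparison = ProfileSpec(
        config.base_temp, config.initial_hold, sign * delta, config.ramp_rate,
        config.stimulus_duration,
    )
    return standard, comparison


def run_block(
    config: StaircaseConfig, obs: ObserverSpec, rng: np.random.Generator
) -> BlockLog:
    """Run one complete adaptive block against a simulated observer.

    Each trial builds the stimulus pair, assigns the changing (or
    larger-changing) stimulus to a random interval, simulates the 2IFC
    response, and applies the staircase update.  Bound clamping never aborts
    the block; it is recorded per trial for post-hoc exclusion.
    """
    criteria = _effective_criteria(obs, config.confidence_scale)
    state = initial_state(config)
    log = BlockLog(config=config)
    for trial_idx in range(config.n_trials):
        delta = min(state.current_delta, config.max_delta)
        clamped = state.current_delta > config.max_delta or (
            state.bound_violation and state.current_delta >= config.max_delta
        )
        standard_spec, comparison_spec = _trial_profiles(config, delta)
        target = int(rng.integers(2))
        profiles = [build_profile(standard_spec), build_profile(comparison_spec)]
        if target == 0:
            profiles.reverse()
        trial = TwoIntervalTrial(profiles=tuple(profiles), target_interval=target)
        resp = simulate_2ifc_trial(trial, obs, rng, criteria=criteria)
        log.records.append(
            TrialRecord(
                trial=trial_idx + 1,
                interval_of_change=target + 1,
                delta_c=delta,
                response_interval=resp.chosen_interval + 1,
                correct=resp.correct,
                confidence=resp.confidence,
                clamped=clamped,
            )
        )
        state = staircase_update(state, resp.correct, config, resp.confidence)
    return log


def estimate_threshold(
    log: BlockLog, config: StaircaseConfig | None = None, block_id: str = ""
) -> ThresholdEstimate:
    """Mean presented delta over the retained (post-convergence) trials."""
    if config is None:
        config = log.config
    if len(log.records) != config.n_trials:
        raise InvalidDesignError(
            f"incomplete block log: {len(log.records)} of {config.n_trials} trials"
        )
    retained = [r.delta_c for r in log.records[config.n_discard:]]
    return ThresholdEstimate(
        value=float(np.mean(retained)),
        direction=config.direction,
        base_temp=config.base_temp,
        n_retained=len(retained),
        block_id=block_id,
        bound_violation=log.bound_violation,
    )


# ---------------------------------------------------------------------------
# Analytic anchors
# ---------------------------------------------------------------------------


def convergence_accuracy(n_down: int) -> float:
    """Percent-correct at which the n-down/1-up rule converges: 0.5**(1/n)."""
    if n_down < 1:
        raise ValueError("n_down must be >= 1")
    return 0.5 ** (1.0 / n_down)


def theoretical_threshold(
    obs: ObserverSpec,
    direction: Direction,
    base_temp: float,
    mode: Mode = "detection",
    reference_delta: float | None = None,
    target_accuracy: float | None = None,
    xtol: float = 1e-6,
) -> float:
    """Delta at which the observer's closed-form accuracy hits the staircase
    convergence point (0.794 for the 3-down/1-up rule), found by bracketed
    root finding.

    Raises
    ------
    ThresholdUnattainableError
        If the accuracy never reaches the target within the temperature
        bounds (e.g. the transducer saturates or the lapse rate is too high).
    """
    if target_accuracy is None:
        target_accuracy = convergence_accuracy(3)
    if direction == "increase":
        max_delta = TEMP_CEILING - base_temp
    else:
        max_delta = base_temp - TEMP_FLOOR
    if mode == "discrimination":
        if reference_delta is None or reference_delta <= 0:
            raise InvalidDesignError("discrimination mode requires reference_delta")

        def p_of(delta: float) -> float:
            return obs_mod.prob_correct_discrimination(
                reference_delta, delta, direction, base_temp, obs
            )

        lo = reference_delta
    else:

        def p_of(delta: float) -> float:
            return obs_mod.prob_correct_detection(delta, direction, base_temp, obs)

        lo = 0.0
    if p_of(max_delta) < target_accuracy:
        raise ThresholdUnattainableError(
            f"accuracy {target_accuracy:.3f} not attainable within bounds "
            f"(max reachable: {p_of(max_delta):.3f})"
        )
    root = brentq(lambda d: p_of(d) - target_accuracy, lo, max_delta, xtol=xtol)
    return float(root)
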
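"""Simulated participants for the 2IFC and rating tasks.

An observer transduces skin temperature to perceived intensity through a
power-law function ``a * max(0, T - T0)**gamma``, compares the perceived
change between the two intervals of a trial under independent Gaussian
decision noise, lapses uniformly at random with a small probability, and
maps its decision variable onto confidence criteria.  With ``gamma == 1``
the transducer is linear; ``gamma > 1`` makes it convex ("positively
accelerating") over the noxious range, which is the mechanism under study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .stimuli import TemperatureProfile, sample_profile

Direction = Literal["increase", "decrease"]

#: Transduction domain (wider than the stimulation bounds so that theoretical
#: probes slightly outside the stimulus range remain evaluable).
TRANSDUCE_MIN = 30.0
TRANSDUCE_MAX = 50.0


@dataclass(frozen=True)
class ObserverSpec:
    """Parameters of one simulated participant.

    Attributes
    ----------
    gain
        Transducer gain ``a`` (perceived-intensity units per Celsius**gamma).
    exponent
        Transducer exponent ``gamma`` (>= 1; 1 = linear).
    offset
        Transduction threshold ``T0`` in Celsius; perceived intensity is 0 at
        or below it.
    noise
        Decision noise sigma (perceived-intensity units, > 0), added
        independently to each interval's perceived-change signal.
    lapse
        Probability of a stimulus-independent uniform random choice, in
        [0, 0.1].
    confidence_criteria
        Strictly increasing non-negative cutoffs on |signal difference|;
        length 1 for the binary confident/guessing report, length 3 for the
        4-point scale.
    rating_intercept, rating_slope, rating_noise
        Affine map (plus Gaussian noise) from perceived intensity to the
        0-10 eVAS used in the rating task.
    """

    gain: float = 1.0
    exponent: float = 1.0
    offset: float = 42.0
    noise: float = 1.0
    lapse: float = 0.0
    confidence_criteria: tuple[float, ...] = (1.0,)
    rating_intercept: float = 0.0
    rating_slope: float = 1.0
    rating_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")
        if self.noise <= 0:
            raise ValueError("noise must be positive")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        crit = self.confidence_criteria
        if len(crit) == 0:
            raise ValueError("confidence_criteria must be non-empty")
        if any(c < 0 for c in crit):
            raise ValueError("confidence criteria must be non-negative")
        if any(b <= a for a, b in zip(crit, crit[1:])):
            raise ValueError("confidence criteria must strictly increase")
        if self.rating_noise < 0:
            raise ValueError("rating_noise must be non-negative")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confidence_criteria"] = list(self.confidence_criteria)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverSpec":
        d = dict(d)
        d["confidence_criteria"] = tuple(d["confidence_criteria"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, payload: str) -> "ObserverSpec":
        return cls.from_dict(json.loads(payload))


def save_cohort(specs: Sequence[ObserverSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=1)


def load_cohort(path) -> list[ObserverSpec]:
    with open(path) as fh:
        return [ObserverSpec.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# Transduction and closed-form choice probabilities
# ---------------------------------------------------------------------------


def transduce(temp_c: float, obs: ObserverSpec) -> float:
    """Perceived intensity ``a * max(0, T - T0)**gamma`` at temperature ``T``."""
    if not (TRANSDUCE_MIN <= temp_c <= TRANSDUCE_MAX):
        raise ValueError(
            f"temperature {temp_c:.2f} C outside transduction domain "
            f"[{TRANSDUCE_MIN}, {TRANSDUCE_MAX}] C"
        )
    drive = temp_c - obs.offset
    if drive <= 0:
        return 0.0
    return obs.gain * drive**obs.exponent


def perceived_change(profile: TemperatureProfile, obs: ObserverSpec) -> float:
    """|perceived end-plateau intensity - perceived start-plateau intensity|."""
    return abs(transduce(profile.end_temp, obs) - transduce(profile.start_temp, obs))


def _signal_to_p(delta_f: float, obs: ObserverSpec) -> float:
    # 2IFC max-rule with independent equal-variance Gaussian noise per interval:
    # P(correct | no lapse) = Phi(delta_f / (sigma * sqrt(2))).
    p_attend = norm.cdf(delta_f / (obs.noise * np.sqrt(2.0)))
    return obs.lapse / 2.0 + (1.0 - obs.lapse) * p_attend


def _check_final_temp(base_temp: float, delta: float, direction: Direction) -> float:
    if delta < 0:
        raise ValueError("delta is an unsigned magnitude; got a negative value")
    final = base_temp + delta if direction == "increase" else base_temp - delta
    from .stimuli import TEMP_FLOOR, TEMP_CEILING

    if not (TEMP_FLOOR <= final <= TEMP_CEILING):
        raise ValueError(
            f"final temperature {final:.2f} C outside "
            f"[{TEMP_FLOOR}, {TEMP_CEILING}] C: invalid staircase state"
        )
    return final


def prob_correct_detection(
    delta: float, direction: Direction, base_temp: float, obs: ObserverSpec
) -> float:
    """Closed-form probability of a correct 2IFC detection response.

    One interval holds ``base_temp`` throughout; the other ends ``delta``
    Celsius above or below it.
    """
    final = _check_final_temp(base_temp, delta, direction)
    delta_f = abs(transduce(final, obs) - transduce(base_temp, obs))
    return float(_signal_to_p(delta_f, obs))


def prob_correct_discrimination(
    delta_small: float,
    delta_large: float,
    direction: Direction,
    base_temp: float,
    obs: ObserverSpec,
) -> float:
    """Closed-form probability of picking the larger of two changes."""
    if delta_large < delta_small:
        raise ValueError("delta_large must be >= delta_small")
    f_base = transduce(base_temp, obs)
    final_small = _check_final_temp(base_temp, delta_small, direction)
    final_large = _check_final_temp(base_temp, delta_large, direction)
    delta_f = abs(transduce(final_large, obs) - f_base) - abs(
        transduce(final_small, obs) - f_base
    )
    return float(_signal_to_p(delta_f, obs))


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoIntervalTrial:
    """One 2IFC trial: two stimulus profiles, the target in one interval.

    ``target_interval`` (0 or 1) indexes the interval containing the change
    (detection) or the larger change (discrimination).
    """

    profiles: tuple[TemperatureProfile, TemperatureProfile]
    target_interval: int

    def __post_init__(self) -> None:
        if self.target_interval not in (0, 1):
            raise ValueError("target_interval must be 0 or 1")


@dataclass(frozen=True)
class TrialResponse:
    chosen_interval: int
    correct: bool
    confidence: int  # 1-based level: 1..2 (binary) or 1..4 (four-point)


def simulate_2ifc_trial(
    trial: TwoIntervalTrial,
    obs: ObserverSpec,
    rng: np.random.Generator,
    criteria: Sequence[float] | None = None,
) -> TrialResponse:
    """Simulate one 2IFC response.

    Each interval contributes a noisy perceived-change signal; the observer
    picks the larger one, lapsing to a uniform random choice with probability
    ``lapse``.  Confidence is the count of criteria exceeded by the absolute
    signal difference, plus one.  ``criteria`` overrides the observer's own
    cutoffs (used when a design collapses a 4-point observer to the binary
    report).
    """
    if criteria is None:
        criteria = obs.confidence_criteria
    signals = [
        perceived_change(p, obs) + rng.normal(0.0, obs.noise) for p in trial.profiles
    ]
    chosen = int(signals[1] > signals[0])
    if obs.lapse > 0 and rng.random() < obs.lapse:
        chosen = int(rng.integers(2))
    diff = abs(signals[0] - signals[1])
    confidence = 1 + sum(1 for c in criteria if diff > c)
    return TrialResponse(
        chosen_interval=chosen,
        correct=chosen == trial.target_interval,
        confidence=confidence,
    )


def simulate_rating(
    profile: TemperatureProfile,
    probe_time: float,
    obs: ObserverSpec,
    rng: np.random.Generator,
) -> float:
    """eVAS rating (0-10) of perceived intensity at ``probe_time``.

    The observer is memoryless: the rating depends only on the temperature at
    the probe, not on the preceding time course.
    """
    perceived = transduce(sample_profile(profile, probe_time), obs)
    raw = (
        obs.rating_intercept
        + obs.rating_slope * perceived
        + (rng.normal(0.0, obs.rating_noise) if obs.rating_noise > 0 else 0.0)
    )
    return float(min(10.0, max(0.0, raw)))
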
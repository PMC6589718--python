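"""Trapezoidal temperature time courses for thermal stimulation.

Every stimulus used by the threshold and rating tasks is a hold → linear
ramp → hold trapezoid (or a constant plateau when the ramp size is zero).
Profiles are continuous in time; any discretization (plotting, CSV export)
is a caller choice, defaulting to 100 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

#: Global safety bounds on skin-surface temperature, in Celsius.
TEMP_FLOOR = 35.0
TEMP_CEILING = 50.0

DEFAULT_SAMPLE_RATE_HZ = 100.0


class InvalidDesignError(ValueError):
    """A stimulus or experiment specification violates its constraints."""


@dataclass(frozen=True)
class ProfileSpec:
    """Parametric description of a single hold-ramp-hold stimulus.

    Parameters
    ----------
    start_temp
        Initial plateau temperature in Celsius.
    initial_hold
        Duration of the initial plateau in seconds.
    delta
        Signed temperature change in Celsius; 0 for a constant stimulus.
    ramp_rate
        Absolute rate of temperature change in Celsius/s, > 0.
    total_duration
        Total stimulus duration in seconds.
    """

    start_temp: float
    initial_hold: float
    delta: float
    ramp_rate: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise InvalidDesignError("total_duration must be positive")
        if self.initial_hold < 0:
            raise InvalidDesignError("initial_hold must be non-negative")
        if self.ramp_rate <= 0:
            raise InvalidDesignError("ramp_rate must be positive")
        end = self.start_temp + self.delta
        for label, temp in (("start", self.start_temp), ("end", end)):
            if not (TEMP_FLOOR <= temp <= TEMP_CEILING):
                raise InvalidDesignError(
                    f"{label} temperature {temp:.2f} C outside "
                    f"[{TEMP_FLOOR}, {TEMP_CEILING}] C"
                )
        ramp_end = self.initial_hold + abs(self.delta) / self.ramp_rate
        if ramp_end > self.total_duration + 1e-12:
            raise InvalidDesignError(
                f"ramp ends at {ramp_end:.3f} s, after total_duration "
                f"{self.total_duration:.3f} s"
            )

    @property
    def end_temp(self) -> float:
        return self.start_temp + self.delta

    @property
    def ramp_end_time(self) -> float:
        return self.initial_hold + abs(self.delta) / self.ramp_rate


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-linear temperature time course.

    ``breakpoints`` is an ordered tuple of ``(time_s, temp_c)`` pairs with
    strictly increasing times starting at 0.  The last breakpoint is the
    stimulus end; the profile is undefined after it.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 2:
            raise InvalidDesignError("a profile needs at least two breakpoints")
        times = [t for t, _ in self.breakpoints]
        temps = [x for _, x in self.breakpoints]
        if times[0] != 0:
            raise InvalidDesignError("first breakpoint time must be 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidDesignError("breakpoint times must strictly increase")
        if any(not (TEMP_FLOOR <= x <= TEMP_CEILING) for x in temps):
            raise InvalidDesignError(
                f"temperatures must lie in [{TEMP_FLOOR}, {TEMP_CEILING}] C"
            )

    @property
    def duration(self) -> float:
        return self.breakpoints[-1][0]

    @property
    def start_temp(self) -> float:
        return self.breakpoints[0][1]

    @property
    def end_temp(self) -> float:
        return self.breakpoints[-1][1]

    @property
    def final_plateau_duration(self) -> float:
        """Length of the trailing constant segment, 0 if the profile ends mid-ramp."""
        (t_prev, x_prev), (t_last, x_last) = self.breakpoints[-2:]
        if x_prev == x_last:
            return t_last - t_prev
        return 0.0

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"breakpoints": [[t, x] for t, x in self.breakpoints]})

    @classmethod
    def from_json(cls, payload: str) -> "TemperatureProfile":
        record = json.loads(payload)
        return cls(tuple((float(t), float(x)) for t, x in record["breakpoints"]))

    def sample_trace(self, rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> pd.DataFrame:
        """Sample the profile on a regular grid (columns time_s, temp_c)."""
        n = int(round(self.duration * rate_hz)) + 1
        times = np.linspace(0.0, self.duration, n)
        temps = [sample_profile(self, t) for t in times]
        return pd.DataFrame({"time_s": times, "temp_c": temps})

    def to_csv(self, path, rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> None:
        self.sample_trace(rate_hz).to_csv(path, index=False)


def build_profile(spec: ProfileSpec) -> TemperatureProfile:
    """Construct the trapezoidal profile described by ``spec``.

    Constant stimuli (``delta == 0``) yield a two-breakpoint plateau; changing
    stimuli yield up to four breakpoints (start, ramp start, ramp end, end).
    Degenerate segments (zero-length hold, ramp ending exactly at the stimulus
    end) are collapsed.
    """
    end_temp = spec.start_temp + spec.delta
    if spec.delta == 0:
        points = [(0.0, spec.start_temp), (spec.total_duration, spec.start_temp)]
    else:
        points = [
            (0.0, spec.start_temp),
            (spec.initial_hold, spec.start_temp),
            (spec.ramp_end_time, end_temp),
            (spec.total_duration, end_temp),
        ]
    deduped: list[tuple[float, float]] = [points[0]]
    for t, x in points[1:]:
        if t > deduped[-1][0] + 1e-12:
            deduped.append((t, x))
    return TemperatureProfile(tuple(deduped))


def sample_profile(profile: TemperatureProfile, t: float) -> float:
    """Temperature at time ``t`` by linear interpolation between breakpoints."""
    if not (0.0 <= t <= profile.duration + 1e-12):
        raise InvalidDesignError(
            f"t={t:.4f} s outside profile domain [0, {profile.duration:.4f}] s"
        )
    times = [p[0] for p in profile.breakpoints]
    temps = [p[1] for p in profile.breakpoints]
    return float(np.interp(t, times, temps))


def profiles_to_json(profiles: Iterable[TemperatureProfile]) -> str:
    return json.dumps(
        [{"breakpoints": [[t, x] for t, x in p.breakpoints]} for p in profiles]
    )


def profiles_from_json(payload: str) -> list[TemperatureProfile]:
    return [
        TemperatureProfile(tuple((float(t), float(x)) for t, x in rec["breakpoints"]))
        for rec in json.loads(payload)
    ]
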
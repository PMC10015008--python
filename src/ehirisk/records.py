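"""Domain record types for runner-level race data and daily course weather.

The interchange schema is a minimal explicit contract (regulatory databases
are not public): CSV with a documented header, ISO-8601 dates, 24-hour
"HH:MM" times.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date, time as _time

RACE_TYPES = ("flat", "jump")
SEXES = ("filly", "colt", "gelding", "stallion", "rig")

#: The ten raw going categories: seven turf descriptors and three
#: all-weather descriptors.
GOING_RAW = (
    "hard",
    "firm",
    "good to firm",
    "good",
    "good to soft",
    "soft",
    "heavy",
    "standard",
    "standard to slow",
    "slow",
    "fast",  # all-weather "fast": meets run on it are excluded outright
)

GOING5 = ("firm", "good", "soft", "heavy", "standard")


class SchemaError(ValueError):
    """A CSV header or field value violates the documented schema."""


@dataclass(frozen=True, slots=True)
class RunnerRecord:
    """One horse performance (a runner) with race, horse and outcome fields."""

    horse_id: str
    meet_id: str
    course_id: str
    race_id: str
    date: _date
    off_time: _time
    distance: float  # yards
    race_type: str
    going_raw: str
    age: int
    sex: str
    ehi: int  # 1 = exertional heat illness incident recorded

    def __post_init__(self):
        if self.distance <= 0:
            raise SchemaError(f"distance must be positive, got {self.distance}")
        if self.age < 1:
            raise SchemaError(f"age must be >= 1, got {self.age}")
        if self.ehi not in (0, 1):
            raise SchemaError(f"ehi must be 0 or 1, got {self.ehi}")
        if self.race_type not in RACE_TYPES:
            raise SchemaError(f"unknown race_type {self.race_type!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.going_raw not in GOING_RAW:
            raise SchemaError(f"unknown going {self.going_raw!r}")


@dataclass(frozen=True, slots=True)
class WeatherDay:
    """Daily maximum air temperature (°C) and relative humidity (%) for one
    course-date."""

    course_id: str
    date: _date
    tmax: float
    rh: float

    def __post_init__(self):
        if not (0.0 <= self.rh <= 100.0):
            raise SchemaError(f"relative humidity outside [0, 100]: {self.rh}")
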
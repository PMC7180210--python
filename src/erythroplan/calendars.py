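"""Treatment calendars, safety bounds, and schedule containers.

A calendar discretizes a planning horizon into an equidistant grid of
``N + 1`` points with step ``dt`` [day].  Calendar day ``d`` (1-based) maps
to grid index ``(d - 1) / dt``, i.e. the first grid point of that day; one
treatment opportunity exists per allowed day.  The *allowed set* ``T`` is
the set of grid indices where a phlebotomy may be placed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .exceptions import InvalidParameterError, ScheduleMismatchError
from .model import DEFAULT_DT, DEFAULT_V_MAX

__all__ = [
    "WEEKDAYS",
    "TreatmentCalendar",
    "SafetyBounds",
    "Schedule",
    "RelaxedControl",
    "build_general_test_calendar",
    "build_weekday_calendar",
    "build_unconstrained_calendar",
    "validate_schedule",
]

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Blocked windows of the general test setup (inclusive calendar days):
#: reduced clinic staffing around the winter and summer holidays.
GENERAL_BLOCKED_DAYS = ((81, 95), (280, 301))


def _steps_per_day(dt: float) -> int:
    spd = round(1.0 / dt)
    if abs(spd * dt - 1.0) > 1e-9:
        raise InvalidParameterError("dt must divide 1 day")
    return spd


@dataclass(frozen=True)
class TreatmentCalendar:
    """Discretized horizon with the set of admissible treatment indices.

    ``allowed`` is a sorted tuple of grid indices; ``dwell`` is the minimal
    index distance between two consecutive treatments (default: one day's
    worth of grid steps).
    """

    n_points: int                      # grid has indices 0..n_points
    dt: float
    allowed: Tuple[int, ...]
    dwell: int
    horizon_days: int

    def __post_init__(self) -> None:
        if self.dwell < 0:
            raise InvalidParameterError("dwell must be non-negative")
        bad = [i for i in self.allowed if not 0 <= i <= self.n_points]
        if bad:
            raise InvalidParameterError(f"allowed indices outside grid: {bad[:3]}")

    @property
    def allowed_set(self) -> frozenset:
        return frozenset(self.allowed)

    def day_of_index(self, i: int) -> int:
        """1-based calendar day containing grid index ``i``."""
        return int(i * self.dt) + 1

    def weekday_of_index(self, i: int) -> str:
        return WEEKDAYS[(self.day_of_index(i) - 1) % 7]

    def index_of_day(self, day: int) -> int:
        """Grid index of the first point of 1-based calendar day ``day``."""
        return (day - 1) * _steps_per_day(self.dt)

    def restrict(self, blocked_days: Iterable[Tuple[int, int]]) -> "TreatmentCalendar":
        """Calendar with additional inclusive blocked day windows removed."""
        blocked = set()
        for lo, hi in blocked_days:
            blocked.update(range(lo, hi + 1))
        keep = tuple(i for i in self.allowed if self.day_of_index(i) not in blocked)
        return TreatmentCalendar(self.n_points, self.dt, keep, self.dwell, self.horizon_days)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "dt": self.dt,
            "allowed": list(self.allowed),
            "dwell": self.dwell,
            "horizon_days": self.horizon_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentCalendar":
        return cls(
            int(d["n_points"]), float(d["dt"]), tuple(int(i) for i in d["allowed"]),
            int(d["dwell"]), int(d["horizon_days"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "TreatmentCalendar":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SafetyBounds:
    """Upper and lower bounds on the total hemoglobin mass x3 [g]."""

    x3_up: float
    x3_lo: float

    def __post_init__(self) -> None:
        if not 0 < self.x3_lo < self.x3_up:
            raise InvalidParameterError("require 0 < x3_lo < x3_up")

    @classmethod
    def default_for(cls, B: float, up_factor: float = 1.10, lo_factor: float = 0.85) -> "SafetyBounds":
        """Repository defaults relative to the healthy base value.

        ``x3_up = 1.1 B`` and ``x3_lo = 0.85 B``: one standard 500 ml
        phlebotomy at a typical 5.5 l blood volume removes about 9% of x3,
        so a withdrawal triggered at the upper bound lands safely above the
        lower one.
        """
        return cls(x3_up=up_factor * B, x3_lo=lo_factor * B)


@dataclass
class Schedule:
    """Binary treatment indicators aligned to a calendar grid."""

    U: np.ndarray
    v_max: float = DEFAULT_V_MAX

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.int8)
        if not np.all((self.U == 0) | (self.U == 1)):
            raise InvalidParameterError("indicators must be 0/1")

    @property
    def n_treatments(self) -> int:
        return int(self.U.sum())

    @property
    def treatment_indices(self) -> np.ndarray:
        return np.flatnonzero(self.U)

    @classmethod
    def empty(cls, n_points: int, v_max: float = DEFAULT_V_MAX) -> "Schedule":
        return cls(np.zeros(n_points + 1, dtype=np.int8), v_max)

    @classmethod
    def from_indices(cls, indices, n_points: int, v_max: float = DEFAULT_V_MAX) -> "Schedule":
        U = np.zeros(n_points + 1, dtype=np.int8)
        U[list(indices)] = 1
        return cls(U, v_max)

    def to_json(self, calendar: Optional[TreatmentCalendar] = None) -> str:
        d = {
            "treatment_indices": self.treatment_indices.tolist(),
            "n_points": int(self.U.size - 1),
            "v_max": self.v_max,
        }
        if calendar is not None:
            d["treatment_days"] = [calendar.day_of_index(i) for i in self.treatment_indices]
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "Schedule":
        d = json.loads(s)
        return cls.from_indices(d["treatment_indices"], d["n_points"], d.get("v_max", DEFAULT_V_MAX))


@dataclass
class RelaxedControl:
    """Fractional withdrawal in [0, 1] per grid interval."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.min(initial=0.0) < -1e-12 or self.u.max(initial=0.0) > 1.0 + 1e-12:
            raise InvalidParameterError("relaxed control must lie in [0, 1]")

    @property
    def objective(self) -> float:
        """Placeholder total; use with a dt to obtain the integral."""
        return float(self.u.sum())


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_unconstrained_calendar(
    horizon_days: int, dt: float = DEFAULT_DT, dwell_days: float = 1.0
) -> TreatmentCalendar:
    """Calendar with every grid point admissible (T = I)."""
    spd = _steps_per_day(dt)
    n = horizon_days * spd
    return TreatmentCalendar(
        n_points=n, dt=dt, allowed=tuple(range(n + 1)),
        dwell=round(dwell_days * spd), horizon_days=horizon_days,
    )


def build_weekday_calendar(
    days: Sequence[str],
    horizon_days: int,
    dt: float = DEFAULT_DT,
    dwell_days: float = 1.0,
    blocked_days: Iterable[Tuple[int, int]] = (),
) -> TreatmentCalendar:
    """One treatment opportunity per listed weekday; day 1 is a Monday."""
    if not days:
        raise InvalidParameterError("weekday set must be non-empty")
    unknown = set(days) - set(WEEKDAYS)
    if unknown:
        raise InvalidParameterError(f"unknown weekday codes: {sorted(unknown)}")
    spd = _steps_per_day(dt)
    blocked = set()
    for lo, hi in blocked_days:
        blocked.update(range(lo, hi + 1))
    wanted = {WEEKDAYS.index(d) for d in days}
    allowed = tuple(
        (day - 1) * spd
        for day in range(1, horizon_days + 1)
        if (day - 1) % 7 in wanted and day not in blocked
    )
    return TreatmentCalendar(
        n_points=horizon_days * spd, dt=dt, allowed=allowed,
        dwell=round(dwell_days * spd), horizon_days=horizon_days,
    )


def build_general_test_calendar(dt: float = DEFAULT_DT, dwell_days: float = 1.0) -> TreatmentCalendar:
    """The 365-day reference setup: Mon–Fri allowed, day 1 a Monday,
    clinic closed on days 81–95 and 280–301 (both inclusive)."""
    return build_weekday_calendar(
        ["Mon", "Tue", "Wed", "Thu", "Fri"], 365, dt=dt, dwell_days=dwell_days,
        blocked_days=GENERAL_BLOCKED_DAYS,
    )


def validate_schedule(schedule: Schedule, calendar: TreatmentCalendar) -> Tuple[bool, List[str]]:
    """Check indicator support and dwell spacing against a calendar."""
    if schedule.U.size != calendar.n_points + 1:
        raise ScheduleMismatchError(
            f"schedule length {schedule.U.size} != grid size {calendar.n_points + 1}"
        )
    violations: List[str] = []
    allowed = calendar.allowed_set
    idx = schedule.treatment_indices
    for i in idx:
        if int(i) not in allowed:
            violations.append(f"treatment at disallowed index {int(i)} (day {calendar.day_of_index(int(i))})")
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a < calendar.dwell:
            violations.append(f"dwell violated between indices {int(a)} and {int(b)}")
    return (not violations), violations
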
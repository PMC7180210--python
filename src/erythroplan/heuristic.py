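"""Clinical-practice heuristic scheduling.

Mirrors how phlebotomy is planned on the ward: integrate the patient
forward; the moment the total hemoglobin mass crosses the upper safety
bound, bleed — immediately if the clinic is open and the dwell time since
the last bleed has passed, otherwise shift the bleed to the latest earlier
admissible slot and re-simulate from there.  With an unconstrained calendar
(every grid point admissible) this produces H-schedules; with a clinic
calendar, HC-schedules.

The heuristic does not look at the lower bound while planning; lower-bound
crossings are detected afterwards and reported as infeasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .calendars import (
    SafetyBounds,
    Schedule,
    TreatmentCalendar,
    build_unconstrained_calendar,
)
from .model import (
    DEFAULT_DT,
    DEFAULT_V_MAX,
    PatientParams,
    SystemState,
    Trajectory,
    _rk4_step,
    healthy_steady_state,
)

__all__ = ["HeuristicResult", "heuristic_schedule", "count_treatments_365"]


@dataclass
class HeuristicResult:
    """Outcome of the heuristic planner."""

    schedule: Schedule
    trajectory: Trajectory
    feasible: bool
    n_treatments: int
    reason: str = ""
    lower_violation_indices: List[int] = field(default_factory=list)


def heuristic_schedule(
    params: PatientParams,
    calendar: TreatmentCalendar,
    bounds: SafetyBounds,
    x0: Optional[SystemState] = None,
    v_max: float = DEFAULT_V_MAX,
) -> HeuristicResult:
    """Run the forward check-and-treat heuristic on a calendar.

    A treatment at grid index ``i`` multiplies ``x3`` by
    ``1 - v_max / v_pat`` after the integration step arriving at ``i``.
    When a crossing happens at a non-admissible index, the bleed is shifted
    to the largest unused admissible ``i*`` with ``i* + dwell < i`` that is
    dwell-compatible with every already placed bleed, and the trajectory is
    recomputed from ``i*``.  If no such slot exists, or the same crossing
    re-triggers without progress, the instance is declared infeasible.
    """
    if x0 is None:
        x0 = healthy_steady_state(params)
    n = calendar.n_points
    dt = calendar.dt
    frac = v_max / params.v_pat
    allowed = calendar.allowed_set
    dwell = calendar.dwell
    up = bounds.x3_up

    states: List[tuple] = [None] * (n + 1)
    states[0] = (x0.x1, x0.x2, x0.x3)
    treated: List[int] = []
    treated_set = set()
    seen_triggers = set()
    feasible = True
    reason = ""

    def dwell_ok(j: int) -> bool:
        return all(abs(j - k) >= dwell for k in treated)

    i = 0
    while i < n:
        x1, x2, x3 = _rk4_step(*states[i], params, 0.0, dt)
        i += 1
        if i in treated_set:
            x3 *= 1.0 - frac
        states[i] = (x1, x2, x3)
        if x3 <= up:
            continue
        key = (i, len(treated))
        if key in seen_triggers:
            feasible = False
            reason = f"crossing at index {i} re-triggered without progress"
            break
        seen_triggers.add(key)
        if i in allowed and i not in treated_set and dwell_ok(i):
            x3 *= 1.0 - frac
            states[i] = (x1, x2, x3)
            treated.append(i)
            treated_set.add(i)
            treated.sort()
        else:
            candidates = [
                j for j in allowed
                if j not in treated_set and j + dwell < i and dwell_ok(j)
            ]
            if not candidates:
                feasible = False
                reason = f"no admissible slot before crossing at index {i}"
                break
            j = max(candidates)
            s1, s2, s3 = states[j]
            states[j] = (s1, s2, s3 * (1.0 - frac))
            treated.append(j)
            treated_set.add(j)
            treated.sort()
            i = j  # re-integrate forward from the shifted bleed

    if feasible:
        arr = np.asarray(states, dtype=float)
    else:
        # keep whatever prefix was computed, pad with the last valid state
        filled = [s for s in states if s is not None]
        arr = np.asarray(filled + [filled[-1]] * (n + 1 - len(filled)), dtype=float)
    traj = Trajectory(np.arange(n + 1) * dt, arr)

    lower_hits = [int(k) for k in np.flatnonzero(arr[:, 2] < bounds.x3_lo)]
    if feasible and lower_hits:
        feasible = False
        reason = "lower bound violated (heuristic does not plan for it)"

    sched = Schedule.from_indices(treated, n, v_max=v_max)
    return HeuristicResult(
        schedule=sched,
        trajectory=traj,
        feasible=feasible,
        n_treatments=len(treated),
        reason=reason,
        lower_violation_indices=lower_hits,
    )


def count_treatments_365(
    params: PatientParams,
    bounds: SafetyBounds,
    dt: float = DEFAULT_DT,
    v_max: float = DEFAULT_V_MAX,
    x0: Optional[SystemState] = None,
) -> int:
    """Unconstrained heuristic treatment count over 365 days (H-schedule).

    This is the quantity the in-silico cohort generator's acceptance rule
    looks at.  Returns -1 when the heuristic is infeasible even without
    calendar constraints (so callers can always reject such draws).
    """
    cal = build_unconstrained_calendar(365, dt=dt)
    res = heuristic_schedule(params, cal, bounds, x0=x0, v_max=v_max)
    if not res.feasible:
        return -1
    return res.n_treatments
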
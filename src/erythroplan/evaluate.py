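"""Scoring, comparison and cohort studies of treatment schedules.

All metrics come from exact re-simulation of a schedule on the fine grid:
``d_viol`` is the grid-time (in days) the erythrocyte mass spends above the
upper safety bound, ``t_f`` the post-horizon refill time — how long after
the planning horizon the untreated patient takes to hit the upper bound
again.  Refill-time differences below one integrator step are treated as
zero (deadband): deviations smaller than the step carry no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import SafetyBounds, Schedule, TreatmentCalendar, build_general_test_calendar
from .exceptions import ErythroplanError, InsufficientDataError
from .exact import refill_time
from .heuristic import heuristic_schedule
from .model import (
    DEFAULT_V_MAX,
    PatientParams,
    SystemState,
    healthy_steady_state,
    simulate,
)
from .relaxed import relaxed_schedule_analytic, sum_up_rounding

__all__ = [
    "ScheduleMetrics",
    "ComparisonRecord",
    "score_schedule",
    "compare",
    "violation_regression",
    "run_cohort",
]


@dataclass
class ScheduleMetrics:
    n_treatments: int
    d_viol: float            # days with x3 above the upper bound
    d_viol_lower: float      # days with x3 below the lower bound
    t_f: float               # post-horizon refill time [day]
    feasible: bool           # no violations on re-simulation


@dataclass
class ComparisonRecord:
    n_diff: int              # n_a - n_b
    delta_tf: float          # t_f(a) - t_f(b), deadbanded at one step
    metrics_a: ScheduleMetrics
    metrics_b: ScheduleMetrics


def score_schedule(
    schedule: Schedule,
    params: PatientParams,
    bounds: SafetyBounds,
    calendar: TreatmentCalendar,
    tf_cap: float = 730.0,
    x0: Optional[SystemState] = None,
) -> ScheduleMetrics:
    """Exact re-simulation metrics of a binary schedule."""
    if x0 is None:
        x0 = healthy_steady_state(params)
    dt = calendar.dt
    traj = simulate(params, x0, float(calendar.horizon_days), dt=dt, schedule=schedule)
    tol = 1e-9 * params.B
    over = int(np.count_nonzero(traj.x3 > bounds.x3_up + tol))
    under = int(np.count_nonzero(traj.x3 < bounds.x3_lo - tol))
    tf = refill_time(params, traj.state_at(len(traj) - 1), bounds.x3_up, tf_cap, dt)
    return ScheduleMetrics(
        n_treatments=schedule.n_treatments,
        d_viol=over * dt,
        d_viol_lower=under * dt,
        t_f=tf,
        feasible=(over == 0 and under == 0),
    )


def compare(metrics_a: ScheduleMetrics, metrics_b: ScheduleMetrics, dt: float) -> ComparisonRecord:
    """Pairwise comparison with the refill-time deadband of one step."""
    delta = metrics_a.t_f - metrics_b.t_f
    if abs(delta) < dt:
        delta = 0.0
    return ComparisonRecord(
        n_diff=metrics_a.n_treatments - metrics_b.n_treatments,
        delta_tf=delta,
        metrics_a=metrics_a,
        metrics_b=metrics_b,
    )


def violation_regression(records: Sequence[ComparisonRecord]):
    """OLS of the violation days of method B on the treatment savings.

    Restricted to records with ``n_diff >= 0`` (instances where the second
    method saved treatments).  Returns ``(slope, intercept, r_squared)``.
    """
    pts = [(r.n_diff, r.metrics_b.d_viol) for r in records if r.n_diff >= 0]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 usable records, got {len(pts)}")
    x, y = map(np.asarray, zip(*pts))
    if np.ptp(x) == 0:
        raise InsufficientDataError("n_diff values are constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# cohort studies
# ---------------------------------------------------------------------------

def _method_heuristic(params, calendar, bounds, v_max, **kw):
    res = heuristic_schedule(params, calendar, bounds, v_max=v_max)
    return res.schedule if res.feasible else None


def _method_sur(params, calendar, bounds, v_max, sur_threshold=1e-6, **kw):
    relaxed = relaxed_schedule_analytic(
        params, bounds, float(calendar.horizon_days), dt=calendar.dt, v_max=v_max
    )
    return sum_up_rounding(relaxed, calendar, threshold=sur_threshold, v_max=v_max)


def _method_bnb(params, calendar, bounds, v_max, bnb_config=None, **kw):
    from .relaxed import bnb_rounding

    relaxed = relaxed_schedule_analytic(
        params, bounds, float(calendar.horizon_days), dt=calendar.dt, v_max=v_max
    )
    res = bnb_rounding(relaxed, params, calendar, bounds, config=bnb_config, v_max=v_max)
    return res.schedule


def _method_miocp(params, calendar, bounds, v_max, tf_cap=730.0, **kw):
    from .exact import miocp_schedule

    res = miocp_schedule(params, calendar, bounds, tf_cap=tf_cap, v_max=v_max)
    return res.schedule


def _method_dp(params, calendar, bounds, v_max, dp_config=None, **kw):
    from .exact import dp_schedule

    res = dp_schedule(params, calendar, bounds, config=dp_config, v_max=v_max)
    return res.schedule


METHODS: Dict[str, Callable] = {
    "heuristic": _method_heuristic,
    "sur": _method_sur,
    "bnb": _method_bnb,
    "miocp": _method_miocp,
    "dp": _method_dp,
}


def run_cohort(
    methods: Sequence[str],
    cohort: Sequence[PatientParams],
    calendar: Optional[TreatmentCalendar] = None,
    bounds: Optional[SafetyBounds] = None,
    tf_cap: float = 730.0,
    v_max: float = DEFAULT_V_MAX,
    **method_kwargs,
):
    """Score several scheduling methods across a cohort.

    Per-configuration safety bounds default to ``SafetyBounds.default_for``
    of each patient's base value.  Individual method failures (infeasible,
    capacity exceeded, solver failure) are recorded, not fatal.

    Returns ``(table, summary)``: a per-row DataFrame and a per-method
    aggregate dict with mean +/- sample sd of the treatment count and the
    violation days, plus feasibility counts.
    """
    if calendar is None:
        calendar = build_general_test_calendar()
    unknown = set(methods) - METHODS.keys()
    if unknown:
        raise ErythroplanError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for params in cohort:
        b = bounds if bounds is not None else SafetyBounds.default_for(params.B)
        for name in methods:
            row = {
                "subject": params.subject_id,
                "lambda_pv": params.lambda_pv,
                "method": name,
                "computed": False,
                "feasible": False,
                "n_treatments": np.nan,
                "d_viol": np.nan,
                "t_f": np.nan,
                "error": "",
            }
            try:
                sched = METHODS[name](params, calendar, b, v_max, **method_kwargs)
            except ErythroplanError as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                continue
            if sched is None:
                row["error"] = "no feasible schedule"
                rows.append(row)
                continue
            m = score_schedule(sched, params, b, calendar, tf_cap=tf_cap)
            row.update(
                computed=True,
                feasible=m.feasible,
                n_treatments=m.n_treatments,
                d_viol=m.d_viol,
                t_f=m.t_f,
            )
            rows.append(row)
    table = pd.DataFrame(rows)
    summary = {}
    for name in methods:
        sub = table[(table["method"] == name) & table["computed"]]
        summary[name] = {
            "n_computed": int(sub.shape[0]),
            "n_feasible": int(sub["feasible"].sum()),
            "n_mean": float(sub["n_treatments"].mean()) if len(sub) else np.nan,
            "n_sd": float(sub["n_treatments"].std(ddof=1)) if len(sub) > 1 else np.nan,
            "d_viol_mean": float(sub["d_viol"].mean()) if len(sub) else np.nan,
            "d_viol_sd": float(sub["d_viol"].std(ddof=1)) if len(sub) > 1 else np.nan,
        }
    return table, summary
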
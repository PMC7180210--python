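"""Relaxed (continuous) optimal phlebotomy and integer rounding schemes.

The continuous optimal control problem minimizes the total withdrawn blood
volume ``\\int u dt`` subject to keeping the erythrocyte mass between the
safety bounds.  Its solution has bang-path structure: ``u = 0`` while
``x3 < X3_up`` and, once the trajectory touches the upper bound, exactly the
withdrawal rate that holds it there,

    u_path = beta * (k2 * x2 - alpha * X3_up) * v_pat / (v_max * X3_up),

obtained by zeroing the erythrocyte balance at ``x3 = X3_up``.

Two routes to this solution are provided: the closed-form state-feedback
law above (valid on calendars without blocked windows), and a direct
single-shooting NLP discretization (one control per day, forward RK4 with
exact sensitivities of the discrete scheme, solved with SLSQP) that also
handles blocked windows by pre-emptive withdrawal.

Binary schedules are then derived either by sum-up rounding (SUR) or by a
branch-and-bound combinatorial integral approximation (CIA) that prunes
nodes whose forward-integrated state leaves the safety corridor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .calendars import RelaxedControl, Schedule, TreatmentCalendar, build_unconstrained_calendar
from .exceptions import CapacityExceededError, InvalidParameterError, SolverFailureError
from .model import (
    DEFAULT_DT,
    DEFAULT_V_MAX,
    PatientParams,
    SystemState,
    Trajectory,
    _rk4_step,
    healthy_steady_state,
    simulate,
)

__all__ = [
    "RelaxedSolution",
    "BnBConfig",
    "BnBResult",
    "path_control",
    "relaxed_schedule_analytic",
    "relaxed_schedule_nlp",
    "sum_up_rounding",
    "bnb_rounding",
]

SUR_EPSILON = 1e-6   # default SUR threshold: treat as soon as any mass accrues
SUR_STANDARD = 0.5   # textbook threshold


@dataclass
class RelaxedSolution:
    """Continuous control, its trajectory, and the objective ``\\int u dt``."""

    control: RelaxedControl
    trajectory: Trajectory
    objective: float
    dt: float


def path_control(
    x2: float, params: PatientParams, x3_up: float, v_max: float = DEFAULT_V_MAX
) -> float:
    """Withdrawal rate fraction that holds ``x3`` exactly at the bound."""
    c = params.constants
    return (
        params.beta * (c.k2 * x2 - c.alpha * x3_up) * params.v_pat / (v_max * x3_up)
    )


def relaxed_schedule_analytic(
    params: PatientParams,
    bounds,
    horizon: float,
    dt: float = DEFAULT_DT,
    v_max: float = DEFAULT_V_MAX,
    x0: Optional[SystemState] = None,
) -> RelaxedSolution:
    """Closed-form bang-path control on a block-free calendar.

    Integrates with ``u = 0`` until the trajectory reaches ``X3_up`` and
    thereafter applies ``u_path`` (clipped to [0, 1]); raises
    :class:`CapacityExceededError` when even ``u = 1`` cannot hold the
    bound (the trajectory escapes above it).
    """
    if x0 is None:
        x0 = healthy_steady_state(params)
    if x0.x3 > bounds.x3_up * (1 + 1e-12):
        raise InvalidParameterError("x0 must start at or below the upper bound")
    up = bounds.x3_up
    n_steps = round(horizon / dt)
    cmax = v_max / params.v_pat
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 3))
    u_out = np.zeros(n_steps)
    x1, x2, x3 = x0.x1, x0.x2, x0.x3
    out[0] = (x1, x2, x3)
    on_bound_tol = 1e-9 * up
    escape_tol = 2e-3 * up
    for i in range(n_steps):
        if x3 >= up - on_bound_tol:
            u = min(max(path_control(x2, params, up, v_max), 0.0), 1.0)
        else:
            u = 0.0
        u_out[i] = u
        x1, x2, x3 = _rk4_step(x1, x2, x3, params, cmax * u, dt)
        if x3 > up + escape_tol:
            raise CapacityExceededError(
                "full continuous withdrawal cannot hold the upper bound "
                f"(x3 reached {x3:.2f} > X3_up {up:.2f})"
            )
        out[i + 1] = (x1, x2, x3)
    return RelaxedSolution(
        control=RelaxedControl(u_out),
        trajectory=Trajectory(times, out),
        objective=float(u_out.sum() * dt),
        dt=dt,
    )


# ---------------------------------------------------------------------------
# direct NLP with forward sensitivities
# ---------------------------------------------------------------------------

def _jacobian(x1, x2, x3, p: PatientParams, uc: float) -> np.ndarray:
    """State Jacobian of the PV right-hand side; ``uc = u * v_max / v_pat``."""
    c = p.constants
    lam = p.lambda_pv
    fb = p.gamma * (1.0 - x3 / p.B)
    return np.array(
        [
            [-p.beta * c.k1 + (1.0 - lam) * fb + lam * p.gamma_star, 0.0,
             -(1.0 - lam) * p.gamma * x1 / p.B],
            [p.beta * c.k1, -p.beta * c.k2, 0.0],
            [0.0, p.beta * c.k2, -p.beta * c.alpha - uc],
        ]
    )


def _sweep_with_sensitivities(
    params: PatientParams,
    x0: SystemState,
    u_days: np.ndarray,
    day_of_var: np.ndarray,
    n_days: int,
    spd: int,
    dt: float,
    v_max: float,
):
    """Integrate with day-wise constant control; return daily x3 and its
    Jacobian wrt the decision variables (exact derivative of the RK4 map)."""
    from .model import _rhs

    m = u_days.size
    cmax = v_max / params.v_pat
    var_of_day = -np.ones(n_days, dtype=int)
    var_of_day[day_of_var] = np.arange(m)
    x = np.array([x0.x1, x0.x2, x0.x3])
    S = np.zeros((3, m))
    x3_days = np.empty(n_days + 1)
    S3_days = np.zeros((n_days + 1, m))
    x3_days[0] = x[2]
    h = 0.5 * dt
    for d in range(n_days):
        a = var_of_day[d]
        uc = cmax * u_days[a] if a >= 0 else 0.0
        for _ in range(spd):
            k1 = np.array(_rhs(x[0], x[1], x[2], params, uc))
            J1 = _jacobian(x[0], x[1], x[2], params, uc)
            dK1 = J1 @ S
            if a >= 0:
                dK1[2, a] += -cmax * x[2]
            xs = x + h * k1
            k2 = np.array(_rhs(xs[0], xs[1], xs[2], params, uc))
            J2 = _jacobian(xs[0], xs[1], xs[2], params, uc)
            dK2 = J2 @ (S + h * dK1)
            if a >= 0:
                dK2[2, a] += -cmax * xs[2]
            xs = x + h * k2
            k3 = np.array(_rhs(xs[0], xs[1], xs[2], params, uc))
            J3 = _jacobian(xs[0], xs[1], xs[2], params, uc)
            dK3 = J3 @ (S + h * dK2)
            if a >= 0:
                dK3[2, a] += -cmax * xs[2]
            xs = x + dt * k3
            k4 = np.array(_rhs(xs[0], xs[1], xs[2], params, uc))
            J4 = _jacobian(xs[0], xs[1], xs[2], params, uc)
            dK4 = J4 @ (S + dt * dK3)
            if a >= 0:
                dK4[2, a] += -cmax * xs[2]
            x = x + (dt / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
            S = S + (dt / 6.0) * (dK1 + 2.0 * (dK2 + dK3) + dK4)
        x3_days[d + 1] = x[2]
        S3_days[d + 1] = S[2]
    return x3_days, S3_days


def relaxed_schedule_nlp(
    params: PatientParams,
    calendar: TreatmentCalendar,
    bounds,
    x0: Optional[SystemState] = None,
    v_max: float = DEFAULT_V_MAX,
    max_iter: int = 200,
    ftol: float = 1e-10,
) -> RelaxedSolution:
    """Direct single-shooting solution of the relaxed OCP.

    One decision variable per *controllable day* (a day containing an
    admissible index), held constant over that day and fixed to zero
    elsewhere; state bounds are imposed at every day boundary.  Because the
    bounds apply across blocked windows, the optimizer withdraws
    pre-emptively before a window when needed.
    """
    if x0 is None:
        x0 = healthy_steady_state(params)
    dt = calendar.dt
    spd = round(1.0 / dt)
    n_days = calendar.horizon_days
    ctrl_days = sorted({calendar.day_of_index(i) - 1 for i in calendar.allowed})
    day_of_var = np.asarray(ctrl_days, dtype=int)
    m = day_of_var.size
    if m == 0:
        raise InvalidParameterError("calendar has no admissible days")

    up, lo = bounds.x3_up, bounds.x3_lo
    scale = params.B

    cache = {}

    def sweep(u):
        key = u.tobytes()
        if key not in cache:
            cache.clear()
            cache[key] = _sweep_with_sensitivities(
                params, x0, u, day_of_var, n_days, spd, dt, v_max
            )
        return cache[key]

    def f_obj(u):
        return float(u.sum())

    def g_obj(u):
        return np.ones(m)

    def f_cons(u):
        x3_days, _ = sweep(u)
        return np.concatenate([(up - x3_days) / scale, (x3_days - lo) / scale])

    def g_cons(u):
        _, S3 = sweep(u)
        return np.vstack([-S3 / scale, S3 / scale])

    # warm start from the analytic feedback law (clipped, blocked days zeroed)
    try:
        ana = relaxed_schedule_analytic(
            params, bounds, float(n_days), dt=dt, v_max=v_max, x0=x0
        )
        u_fine = ana.control.u
    except CapacityExceededError:
        u_fine = np.full(n_days * spd, 0.5)
    u0 = np.array([u_fine[d * spd:(d + 1) * spd].mean() for d in day_of_var])

    res = minimize(
        f_obj,
        u0,
        jac=g_obj,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "ineq", "fun": f_cons, "jac": g_cons}],
        options={"maxiter": max_iter, "ftol": ftol},
    )
    cons_min = f_cons(res.x).min()
    if not res.success and cons_min < -1e-5:
        raise SolverFailureError(
            f"SLSQP failed: {res.message} (worst constraint {cons_min:.2e})"
        )

    u_days = np.clip(res.x, 0.0, 1.0)
    u_full = np.zeros(n_days * spd)
    for a, d in enumerate(day_of_var):
        u_full[d * spd:(d + 1) * spd] = u_days[a]
    traj = simulate(params, x0, float(n_days), dt=dt, control=u_full, v_max=v_max)
    return RelaxedSolution(
        control=RelaxedControl(u_full),
        trajectory=traj,
        objective=float(u_full.sum() * dt),
        dt=dt,
    )


# ---------------------------------------------------------------------------
# sum-up rounding
# ---------------------------------------------------------------------------

def sum_up_rounding(
    relaxed: RelaxedSolution,
    calendar: TreatmentCalendar,
    threshold: float = SUR_EPSILON,
    v_max: float = DEFAULT_V_MAX,
) -> Schedule:
    """Sum-up rounding of a relaxed control onto a treatment calendar.

    The recursion runs on the treatment-opportunity grid (one slot per
    calendar day): the relaxed control is first aggregated into per-day
    withdrawal mass ``u*_d = \\int_day u dt`` (in days of full-rate
    withdrawal — one binary phlebotomy is worth exactly one such unit),
    and walking left to right a treatment is placed at the slot of day
    ``d`` when

        ``U_d = 1  iff  sum_{d'<=d} u*_d' - sum_{d'<d} U_d' >= u_T``.

    Days without an admissible slot are forced to zero; the accumulator
    keeps running, so withheld mass is released at the next open slot.
    With a day-resolution relaxed grid (``dt = 1``) this is the textbook
    recursion evaluated value by value.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError("threshold must lie in (0, 1]")
    u = relaxed.control.u
    n = u.size
    if calendar.n_points != n:
        raise InvalidParameterError("relaxed control and calendar grids differ")
    dt = calendar.dt
    spd = round(1.0 / dt)
    n_days = calendar.horizon_days
    allowed = calendar.allowed_set
    # slot index of each day, -1 where the clinic is closed
    slot = np.full(n_days, -1, dtype=int)
    for i in allowed:
        d = calendar.day_of_index(i) - 1
        if d < n_days:
            slot[d] = i
    U = np.zeros(n + 1, dtype=np.int8)
    acc = 0.0
    placed = 0
    for d in range(n_days):
        acc += u[d * spd:(d + 1) * spd].sum() * dt
        if slot[d] >= 0 and acc - placed >= threshold:
            U[slot[d]] = 1
            placed += 1
    return Schedule(U, v_max=v_max)


# ---------------------------------------------------------------------------
# branch-and-bound combinatorial integral approximation
# ---------------------------------------------------------------------------

@dataclass
class BnBConfig:
    """Budget and ordering knobs for the CIA branch-and-bound."""

    max_iterations: int = 5_000_000
    small_preset: int = 500_000
    bound_tol_factor: float = 1e-9   # state-bound slack, relative to B

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be at least 1")


@dataclass
class BnBResult:
    schedule: Optional[Schedule]
    cost: float
    iterations: int
    status: str  # "optimal" | "capped" | "no_solution"


def bnb_rounding(
    relaxed: RelaxedSolution,
    params: PatientParams,
    calendar: TreatmentCalendar,
    bounds,
    config: Optional[BnBConfig] = None,
    x0: Optional[SystemState] = None,
    v_max: float = DEFAULT_V_MAX,
) -> BnBResult:
    """Branch-and-bound rounding minimizing the CIA deviation.

    The tree branches forward in time over the admissible indices; the node
    cost is the running maximum, taken at the decision points, of the
    accumulated control deviation ``|sum u* dt - sum U|`` in days of
    full-rate withdrawal (one binary phlebotomy is worth one unit).  This
    maximum never decreases along a path and therefore bounds every
    descendant.  Each node's state is forward integrated (treatments as
    instantaneous withdrawals); a branch whose ``x3`` leaves the safety
    corridor before the next decision point is pruned, as is any node
    whose cost already meets the incumbent.  Children are explored
    sum-up-rounding-choice first.
    """
    if config is None:
        config = BnBConfig()
    if x0 is None:
        x0 = healthy_steady_state(params)
    dt = calendar.dt
    u = relaxed.control.u
    n = u.size
    if calendar.n_points != n:
        raise InvalidParameterError("relaxed control and calendar grids differ")
    up, lo = bounds.x3_up, bounds.x3_lo
    tol = config.bound_tol_factor * params.B
    frac = v_max / params.v_pat
    decisions = sorted(calendar.allowed_set)
    dwell = calendar.dwell
    cum_u = np.concatenate(([0.0], np.cumsum(u) * dt))

    def advance(state, sigma, maxdev, start, stop, treat_start):
        """Integrate grid indices [start, stop); apply event at start if asked.
        Returns (state, sigma, maxdev) or None on bound violation."""
        x1, x2, x3 = state
        if treat_start:
            x3 *= 1.0 - frac
            sigma -= 1.0
            if x3 < lo - tol:
                return None
        elif x3 > up + tol:
            # arrival state left untreated: the deferred upper-bound check
            return None
        for j in range(start, stop):
            sigma += u[j] * dt
            x1, x2, x3 = _rk4_step(x1, x2, x3, params, 0.0, dt)
            if x3 < lo - tol:
                return None
            # the segment's final point is the next decision: its upper
            # bound is judged after that decision (a bleed may fire there)
            if j < stop - 1 and x3 > up + tol:
                return None
        # deviation measured at opportunity boundaries: a treatment and the
        # withdrawal mass of its own slot cancel within the segment
        if abs(sigma) > maxdev:
            maxdev = abs(sigma)
        return (x1, x2, x3), sigma, maxdev

    # initial segment: up to the first decision index
    first = decisions[0] if decisions else n
    init = advance((x0.x1, x0.x2, x0.x3), 0.0, 0.0, 0, first, False)
    if init is None:
        return BnBResult(None, np.inf, 0, "no_solution")

    best_cost = np.inf
    best_indices: Optional[Tuple[int, ...]] = None
    iterations = 0
    capped = False

    # stack entries: (pos, state, sigma, maxdev, last_treat_index, chosen)
    stack = [(0, init[0], init[1], init[2], -10**9, ())]
    while stack:
        if iterations >= config.max_iterations:
            capped = True
            break
        pos, state, sigma, maxdev, last, chosen = stack.pop()
        iterations += 1
        if maxdev >= best_cost:
            continue
        if pos == len(decisions):
            # tail beyond last decision already integrated on arrival;
            # the horizon endpoint has no bleed, so check it now
            if state[2] > up + tol:
                continue
            best_cost = maxdev
            best_indices = chosen
            continue
        idx = decisions[pos]
        stop = decisions[pos + 1] if pos + 1 < len(decisions) else n
        children = []
        for U_i in (0, 1):
            if U_i == 1 and idx - last < dwell:
                continue
            nxt = advance(state, sigma, maxdev, idx, stop, U_i == 1)
            if nxt is None:
                continue
            ns, nsig, nmax = nxt
            if nmax >= best_cost:
                continue
            children.append(
                (U_i, (pos + 1, ns, nsig, nmax, idx if U_i else last,
                       chosen + (idx,) if U_i else chosen))
            )
        # SUR-like preferred child explored first -> push it last; the
        # upcoming segment's mass counts towards the decision, as in Eq-15
        prefer = 1 if sigma + (cum_u[stop] - cum_u[idx]) >= SUR_STANDARD else 0
        children.sort(key=lambda c: c[0] == prefer)
        for _, node in children:
            stack.append(node)

    if best_indices is None:
        return BnBResult(None, np.inf, iterations, "capped" if capped else "no_solution")
    sched = Schedule.from_indices(best_indices, n, v_max=v_max)
    return BnBResult(sched, best_cost, iterations, "capped" if capped else "optimal")
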
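"""Exact treatment scheduling: fixed-count search and dynamic programming.

The fixed-count scheduler mirrors the iterative mixed-integer optimal
control idea: start from the constrained-heuristic treatment count, and for
each count enumerate all dwell-respecting placements on the admissible
index set (depth-first, pruning a partial placement as soon as forward
integration leaves the safety corridor before the next open decision
point).  Among feasible placements the one maximizing the post-horizon
refill time ``T_f`` — the first time after the horizon at which ``x3``
again reaches the upper bound, integrating without control — is kept; the
count is decremented while any feasible placement exists.

The dynamic-programming scheduler discretizes the three-dimensional state
space on a regular grid, tabulates the one-stage transition of every grid
state under both control choices (the dynamics are time-invariant, so one
table per distinct stage gap suffices), rounds transition endpoints to the
grid with a configurable offset, and computes the cost-to-go (stage cost =
number of treatments) backwards in time.  Grid rounding means extracted
schedules can violate the true bounds slightly on exact re-simulation; a
positive offset rounds towards higher states, making the planner
conservative (treat earlier, violate less).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .calendars import SafetyBounds, Schedule, TreatmentCalendar
from .exceptions import InvalidParameterError, MemoryBudgetError
from .heuristic import heuristic_schedule
from .model import (
    DEFAULT_V_MAX,
    PatientParams,
    SystemState,
    _rk4_step,
    healthy_steady_state,
    pv_steady_state,
)

__all__ = [
    "MiocpResult",
    "DPConfig",
    "DPResult",
    "refill_time",
    "miocp_schedule",
    "dp_schedule",
]


def refill_time(
    params: PatientParams,
    state: SystemState,
    x3_up: float,
    tf_cap: float = 730.0,
    dt: float = 1.0 / 6.0,
) -> float:
    """First time (from ``state``, integrating without control) at which
    ``x3`` reaches ``x3_up``; linearly interpolated, capped at ``tf_cap``."""
    x1, x2, x3 = state.x1, state.x2, state.x3
    if x3 >= x3_up:
        return 0.0
    t = 0.0
    while t < tf_cap:
        n1, n2, n3 = _rk4_step(x1, x2, x3, params, 0.0, dt)
        t += dt
        if n3 >= x3_up:
            f = (x3_up - x3) / (n3 - x3)
            return t - dt + f * dt
        x1, x2, x3 = n1, n2, n3
    return tf_cap


@dataclass
class MiocpResult:
    schedule: Optional[Schedule]
    n_treatments: int
    t_f: float
    status: str  # "optimal" | "infeasible" | "capped"
    nodes_explored: int = 0


def miocp_schedule(
    params: PatientParams,
    calendar: TreatmentCalendar,
    bounds: SafetyBounds,
    x0: Optional[SystemState] = None,
    tf_cap: float = 730.0,
    v_max: float = DEFAULT_V_MAX,
    max_allowed_points: int = 25,
    node_cap: int = 2_000_000,
) -> MiocpResult:
    """Minimize the treatment count, then maximize the refill time ``T_f``.

    Anytime-correct: interrupting at any count level (node cap) returns the
    best feasible schedule found so far, flagged ``"capped"``.
    """
    if x0 is None:
        x0 = healthy_steady_state(params)
    decisions = sorted(calendar.allowed_set)
    if len(decisions) > max_allowed_points:
        raise InvalidParameterError(
            f"|T| = {len(decisions)} exceeds the enumeration guard "
            f"({max_allowed_points}); use the heuristic or DP instead"
        )
    hres = heuristic_schedule(params, calendar, bounds, x0=x0, v_max=v_max)
    if not hres.feasible:
        return MiocpResult(None, 0, 0.0, "infeasible")
    u_up = hres.n_treatments

    n = calendar.n_points
    dt = calendar.dt
    up, lo = bounds.x3_up, bounds.x3_lo
    tol = 1e-9 * params.B
    frac = v_max / params.v_pat
    dwell = calendar.dwell
    nodes = 0
    capped = False

    def advance(state, start, stop, treat_start):
        x1, x2, x3 = state
        if treat_start:
            x3 *= 1.0 - frac
            if x3 < lo - tol:
                return None
        elif x3 > up + tol:
            return None  # untreated arrival state above the bound
        for j in range(start, stop):
            x1, x2, x3 = _rk4_step(x1, x2, x3, params, 0.0, dt)
            if x3 < lo - tol:
                return None
            # upper bound at the next decision point is judged after that
            # decision (a bleed may fire on arrival)
            if j < stop - 1 and x3 > up + tol:
                return None
        return (x1, x2, x3)

    def search(u_sum: int):
        """Best (t_f, indices) over feasible placements of u_sum bleeds."""
        nonlocal nodes, capped
        first = decisions[0] if decisions else n
        init = advance((x0.x1, x0.x2, x0.x3), 0, first, False)
        if init is None:
            return None
        best: Optional[Tuple[float, Tuple[int, ...]]] = None
        stack = [(0, init, 0, -10**9, ())]
        while stack:
            if nodes >= node_cap:
                capped = True
                break
            pos, state, used, last, chosen = stack.pop()
            nodes += 1
            if pos == len(decisions):
                if used == u_sum and state[2] <= up + tol:
                    tf = refill_time(params, SystemState(*state), up, tf_cap, dt)
                    if best is None or tf > best[0]:
                        best = (tf, chosen)
                continue
            remaining = len(decisions) - pos
            idx = decisions[pos]
            stop = decisions[pos + 1] if pos + 1 < len(decisions) else n
            for U_i in (0, 1):
                if U_i == 1 and (used == u_sum or idx - last < dwell):
                    continue
                if U_i == 0 and used + remaining - 1 < u_sum:
                    continue  # cannot reach the required count anymore
                nxt = advance(state, idx, stop, U_i == 1)
                if nxt is None:
                    continue
                stack.append(
                    (pos + 1, nxt, used + U_i, idx if U_i else last,
                     chosen + (idx,) if U_i else chosen)
                )
        return best

    best_overall: Optional[Tuple[int, float, Tuple[int, ...]]] = None
    u_sum = u_up
    while u_sum >= 0:
        found = search(u_sum)
        if found is None:
            break
        best_overall = (u_sum, found[0], found[1])
        if capped:
            break
        u_sum -= 1

    if best_overall is None:
        return MiocpResult(None, 0, 0.0, "capped" if capped else "infeasible", nodes)
    count, tf, indices = best_overall
    sched = Schedule.from_indices(indices, n, v_max=v_max)
    return MiocpResult(sched, count, tf, "capped" if capped else "optimal", nodes)


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

@dataclass
class DPConfig:
    """State-space discretization for the DP scheduler.

    ``n_grid`` points per state over ``ranges`` (default: from half the
    healthy fixed point up to 1.1x the PV fixed point, with the x3 range
    capped at 1.05 * X3_up); ``offset`` shifts the transition rounding
    towards higher states (conservative planning).
    """

    n_grid: int = 400
    ranges: Optional[Tuple[Tuple[float, float], ...]] = None
    offset: float = 0.0
    memory_cap_bytes: int = 2 * 1024**3

    def __post_init__(self) -> None:
        if self.n_grid < 2:
            raise InvalidParameterError("n_grid must be at least 2")

    def resolve_ranges(
        self,
        params: PatientParams,
        bounds: SafetyBounds,
        x0: SystemState,
        horizon_days: int,
        v_max: float = DEFAULT_V_MAX,
    ) -> Tuple[Tuple[float, float], ...]:
        """State-space box covering the reachable region.

        The precursor compartments transiently overshoot their fixed-point
        values (the feedback drives them above the PV steady state whenever
        ``x3`` is held below ``B_PV``), so fixed-point-based boxes clip
        reachable states.  Instead, a pilot unconstrained-heuristic run
        brackets the treated trajectory and generous margins are added;
        the ``x3`` range spans the whole safety corridor (one post-bound
        withdrawal below it, 5% above it).
        """
        if self.ranges is not None:
            return self.ranges
        from .calendars import build_unconstrained_calendar
        from .heuristic import heuristic_schedule

        cal = build_unconstrained_calendar(horizon_days, dt=1.0 / 6.0)
        pilot = heuristic_schedule(params, cal, bounds, x0=x0, v_max=v_max).trajectory
        frac = v_max / params.v_pat
        lo, hi = [], []
        for k in (0, 1):
            vals = pilot.states[:, k]
            lo.append(0.75 * min(vals.min(), (x0.x1, x0.x2)[k]))
            hi.append(1.25 * max(vals.max(), (x0.x1, x0.x2)[k]))
        lo.append(min(0.95 * (1.0 - frac) * bounds.x3_lo, 0.95 * x0.x3))
        hi.append(max(1.05 * bounds.x3_up, 1.02 * x0.x3))
        return tuple(zip(lo, hi))


@dataclass
class DPResult:
    schedule: Optional[Schedule]
    feasible: bool
    n_treatments: int
    cost: float
    stages: int = 0


def _tabulate_gap(
    params: PatientParams,
    grids: Tuple[np.ndarray, np.ndarray, np.ndarray],
    gap_steps: int,
    dt: float,
    frac: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous endpoints of integrating every grid state over one stage,
    for U = 0 and U = 1 (withdrawal applied at the stage start)."""
    g1, g2, g3 = grids
    X1, X2, X3 = np.meshgrid(g1, g2, g3, indexing="ij")
    base = np.stack([X1.ravel(), X2.ravel(), X3.ravel()])
    ends = []
    for U in (0, 1):
        x1 = base[0].copy()
        x2 = base[1].copy()
        x3 = base[2] * (1.0 - frac) if U else base[2].copy()
        c = params.constants
        lam, beta, gamma, gs, B, X0 = (
            params.lambda_pv, params.beta, params.gamma,
            params.gamma_star, params.B, params.X0,
        )

        def rhs(a, b, d):
            fb = gamma * (1.0 - d / B)
            da = beta * (X0 - c.k1 * a) + ((1.0 - lam) * fb + lam * gs) * a
            db = beta * (c.k1 * a - c.k2 * b)
            dd = beta * (c.k2 * b - c.alpha * d)
            return da, db, dd

        h = 0.5 * dt
        for _ in range(gap_steps):
            a1, b1, d1 = rhs(x1, x2, x3)
            a2, b2, d2 = rhs(x1 + h * a1, x2 + h * b1, x3 + h * d1)
            a3, b3, d3 = rhs(x1 + h * a2, x2 + h * b2, x3 + h * d2)
            a4, b4, d4 = rhs(x1 + dt * a3, x2 + dt * b3, x3 + dt * d3)
            s = dt / 6.0
            x1 = x1 + s * (a1 + 2.0 * (a2 + a3) + a4)
            x2 = x2 + s * (b1 + 2.0 * (b2 + b3) + b4)
            x3 = x3 + s * (d1 + 2.0 * (d2 + d3) + d4)
        ends.append(np.stack([x1, x2, x3]))
    return base, ends[0], ends[1]


def _round_to_grid(
    end: np.ndarray,
    grids: Tuple[np.ndarray, np.ndarray, np.ndarray],
    offset: float,
) -> np.ndarray:
    """Flat grid indices of continuous endpoints; -1 where out of range.

    Rounding shifts by ``offset`` cells towards higher values:
    ``i* = floor((x - min) / dx + offset + 0.5)``.
    """
    n = grids[0].size
    idx = np.empty((3, end.shape[1]), dtype=np.int64)
    valid = np.ones(end.shape[1], dtype=bool)
    for k in range(3):
        g = grids[k]
        dx = g[1] - g[0]
        i = np.floor((end[k] - g[0]) / dx + offset + 0.5).astype(np.int64)
        valid &= (i >= 0) & (i < n)
        idx[k] = np.clip(i, 0, n - 1)
    flat = (idx[0] * n + idx[1]) * n + idx[2]
    flat[~valid] = -1
    return flat


def dp_schedule(
    params: PatientParams,
    calendar: TreatmentCalendar,
    bounds: SafetyBounds,
    x0: Optional[SystemState] = None,
    config: Optional[DPConfig] = None,
    v_max: float = DEFAULT_V_MAX,
) -> DPResult:
    """Globally optimal schedule on the discretized state space.

    Stages sit at the admissible treatment indices; between stages the
    system evolves freely.  Stage cost is the treatment indicator; grid
    states with ``x3`` outside the safety corridor carry infinite
    cost-to-go.  Requires stage spacing of at least the calendar dwell
    (one opportunity per day or sparser), which every day-based calendar
    satisfies.
    """
    if config is None:
        config = DPConfig()
    if x0 is None:
        x0 = healthy_steady_state(params)
    decisions = sorted(calendar.allowed_set)
    if not decisions:
        raise InvalidParameterError("calendar has no admissible indices")
    n = calendar.n_points
    dt = calendar.dt
    frac = v_max / params.v_pat
    ng = config.n_grid

    n_states = ng**3
    gaps = sorted({b - a for a, b in zip(decisions, decisions[1:])} | {n - decisions[-1]})
    gaps = [g for g in gaps if g > 0]
    est = n_states * (len(gaps) * 2 * 8 + 8 + 3 * 8)
    if est > config.memory_cap_bytes:
        raise MemoryBudgetError(
            f"DP tabulation would need about {est / 1e9:.2f} GB "
            f"(cap {config.memory_cap_bytes / 1e9:.2f} GB); reduce n_grid"
        )

    ranges = config.resolve_ranges(params, bounds, x0, calendar.horizon_days, v_max)
    grids = tuple(np.linspace(lo, hi, ng) for lo, hi in ranges)

    trans = {}
    for g in gaps:
        _, e0, e1 = _tabulate_gap(params, grids, g, dt, frac)
        trans[g] = (
            _round_to_grid(e0, grids, config.offset),
            _round_to_grid(e1, grids, config.offset),
        )

    # validity of a grid state: x3 within the safety corridor
    X3 = np.broadcast_to(grids[2], (ng, ng, ng)).ravel()
    valid = (X3 >= bounds.x3_lo) & (X3 <= bounds.x3_up)

    INF = np.inf
    K = len(decisions)
    # terminal: after the gap following the last decision
    J_next = np.where(valid, 0.0, INF)

    # backward over decision stages; keep per-stage policy for extraction
    policy: List[np.ndarray] = [None] * K
    for k in range(K - 1, -1, -1):
        g = (decisions[k + 1] - decisions[k]) if k + 1 < K else (n - decisions[k])
        if g == 0:
            t0 = t1 = np.arange(n_states)  # decision at the final grid point
            J0 = J_next
            J1 = J_next
        else:
            t0, t1 = trans[g]
            J0 = np.where(t0 >= 0, J_next[np.clip(t0, 0, None)], INF)
            J1 = np.where(t1 >= 0, J_next[np.clip(t1, 0, None)], INF)
        J0 = np.where(valid, J0, INF)
        J1 = np.where(valid, 1.0 + J1, INF)
        take = J1 < J0  # strict: ties prefer no treatment
        policy[k] = take
        J_next = np.where(take, J1, J0)

    J_first = J_next  # cost-to-go at the first decision stage

    # initial segment 0 -> decisions[0], no control, continuous from x0
    x = (x0.x1, x0.x2, x0.x3)
    for _ in range(decisions[0]):
        x = _rk4_step(*x, params, 0.0, dt)
    start = _round_to_grid(np.array(x).reshape(3, 1), grids, config.offset)[0]
    if start < 0 or not np.isfinite(J_first[start]):
        return DPResult(None, False, 0, float("inf"), K)

    # forward extraction
    indices = []
    s = int(start)
    for k in range(K):
        take = bool(policy[k][s])
        if take:
            indices.append(decisions[k])
        g = (decisions[k + 1] - decisions[k]) if k + 1 < K else (n - decisions[k])
        if g > 0:
            s = int(trans[g][1 if take else 0][s])
            if s < 0:
                return DPResult(None, False, 0, float("inf"), K)
    cost = float(J_first[start])
    sched = Schedule.from_indices(indices, n, v_max=v_max)
    return DPResult(sched, True, len(indices), cost, K)
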
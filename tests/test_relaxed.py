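import itertools

import numpy as np
import pytest

import erythroplan as ep
from erythroplan.exceptions import CapacityExceededError, InvalidParameterError
from erythroplan.model import rhs_pv
from erythroplan.relaxed import BnBConfig, RelaxedSolution, path_control


class TestAnalyticRelaxed:
    def test_healthy_patient_needs_no_withdrawal(self, subject20, bounds20):
        sol = ep.relaxed_schedule_analytic(subject20.params(0.0), bounds20, 103.0)
        assert sol.objective == 0.0
        assert np.all(sol.control.u == 0.0)

    def test_path_control_zeroes_the_erythrocyte_balance(self, patient20, bounds20):
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 103.0)
        on_bound = np.flatnonzero(
            sol.trajectory.x3 >= bounds20.x3_up * (1 - 1e-6)
        )
        assert on_bound.size > 0
        i = int(on_bound[on_bound.size // 2])
        state = sol.trajectory.state_at(i)
        u = path_control(state.x2, patient20, bounds20.x3_up)
        d = rhs_pv(
            ep.SystemState(state.x1, state.x2, bounds20.x3_up),
            patient20,
            u=min(max(u, 0.0), 1.0),
        )
        assert abs(d.x3) < 1e-8 * patient20.B

    def test_bound_is_tracked_tightly(self, patient20, bounds20):
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 150.0)
        assert sol.trajectory.x3.max() <= bounds20.x3_up * (1 + 5e-4)

    def test_capacity_exhaustion_raises(self, subject20):
        # bounds so low that even continuous full withdrawal cannot hold them
        b = ep.SafetyBounds(x3_up=0.9 * subject20.B, x3_lo=0.5 * subject20.B)
        x0 = ep.SystemState(*ep.healthy_steady_state(subject20.params(0.9)).as_tuple()[:2],
                            0.89 * subject20.B)
        with pytest.raises(CapacityExceededError):
            ep.relaxed_schedule_analytic(subject20.params(0.9), b, 200.0, x0=x0)


class TestNlpRelaxed:
    def test_matches_analytic_solution_without_blocks(self, patient20, bounds20):
        cal = ep.build_weekday_calendar(
            ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], 103
        )
        ana = ep.relaxed_schedule_analytic(patient20, bounds20, 103.0)
        nlp = ep.relaxed_schedule_nlp(patient20, cal, bounds20)
        assert nlp.objective == pytest.approx(ana.objective, rel=5e-3)

    def test_state_bounds_respected(self, patient20, bounds20):
        cal = ep.build_weekday_calendar(
            ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], 60
        )
        nlp = ep.relaxed_schedule_nlp(patient20, cal, bounds20)
        assert nlp.trajectory.x3.max() <= bounds20.x3_up + 2e-5 * patient20.B

    def test_blocked_window_never_decreases_objective(self, subject02):
        # restriction monotonicity on a few burdens
        b = ep.SafetyBounds.default_for(subject02.B)
        for lam in (0.45, 0.55, 0.65):
            p = subject02.params(lam)
            free = ep.build_weekday_calendar(
                ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], 60
            )
            blocked = ep.build_weekday_calendar(
                ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], 60,
                blocked_days=[(35, 48)],
            )
            o_free = ep.relaxed_schedule_nlp(p, free, b).objective
            o_blocked = ep.relaxed_schedule_nlp(p, blocked, b).objective
            assert o_blocked >= o_free - 1e-4 * max(o_free, 1.0)

    def test_anticipates_blocked_window_with_preemptive_withdrawal(self, subject02):
        b = ep.SafetyBounds.default_for(subject02.B)
        p = subject02.params(0.65)
        all_days = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
        # place the window across the first bound crossing of the free problem
        free_sol = ep.relaxed_schedule_analytic(p, b, 60.0)
        first = np.flatnonzero(free_sol.control.u > 0)[0]
        cross_day = int(first * ep.DEFAULT_DT) + 1
        window = (max(1, cross_day - 4), min(60, cross_day + 10))
        blocked = ep.build_weekday_calendar(all_days, 60, blocked_days=[window])
        sol = ep.relaxed_schedule_nlp(p, blocked, b)
        spd = 6
        pre = sol.control.u[: (window[0] - 1) * spd].sum()
        assert pre > 0  # withdrawal moved ahead of the closed window
        assert sol.trajectory.x3.max() <= b.x3_up + 2e-5 * p.B


def day_grid_solution(u_daily):
    """Relaxed solution stub on a 1-day grid (dt = 1)."""
    u = np.asarray(u_daily, dtype=float)
    times = np.arange(u.size + 1, dtype=float)
    states = np.ones((u.size + 1, 3))
    return RelaxedSolution(
        control=ep.RelaxedControl(u),
        trajectory=ep.Trajectory(times, states),
        objective=float(u.sum()),
        dt=1.0,
    )


def day_calendar(n_days):
    return ep.build_weekday_calendar(
        ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], n_days, dt=1.0
    )


class TestSumUpRounding:
    def test_eager_threshold_places_at_first_mass(self):
        sol = day_grid_solution([0, 0, 0.3, 0.4, 0, 0.2])
        sched = ep.sum_up_rounding(sol, day_calendar(6), threshold=1e-6)
        np.testing.assert_array_equal(sched.U[:6], [0, 0, 1, 0, 0, 0])

    def test_standard_threshold_waits_for_half(self):
        sol = day_grid_solution([0, 0, 0.3, 0.4, 0, 0.2])
        sched = ep.sum_up_rounding(sol, day_calendar(6), threshold=0.5)
        np.testing.assert_array_equal(sched.U[:6], [0, 0, 0, 1, 0, 0])

    def test_zero_control_yields_empty_schedule(self):
        sol = day_grid_solution([0.0] * 6)
        sched = ep.sum_up_rounding(sol, day_calendar(6))
        assert sched.n_treatments == 0

    def test_never_treats_before_control_becomes_positive(self, patient20, bounds20):
        cal = ep.build_unconstrained_calendar(103)
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 103.0)
        sched = ep.sum_up_rounding(sol, cal, threshold=1e-6)
        first_mass = np.flatnonzero(sol.control.u > 0)[0]
        first_treat = sched.treatment_indices[0]
        assert first_treat >= first_mass

    def test_blocked_slots_force_zero(self):
        sol = day_grid_solution([0.6, 0.6, 0, 0, 0, 0])
        cal = ep.build_weekday_calendar(["Wed"], 6, dt=1.0)  # only day 3 open
        sched = ep.sum_up_rounding(sol, cal, threshold=0.5)
        assert list(sched.treatment_indices) == [2]

    def test_invalid_threshold_rejected(self):
        sol = day_grid_solution([0.1])
        with pytest.raises(InvalidParameterError):
            ep.sum_up_rounding(sol, day_calendar(1), threshold=0.0)


def bnb_oracle(relaxed, params, calendar, bounds, v_max=ep.DEFAULT_V_MAX):
    """Exhaustive minimization of the day-unit CIA deviation over all
    dwell-respecting, state-feasible binary schedules."""
    u = relaxed.control.u
    dt = calendar.dt
    decisions = sorted(calendar.allowed_set)
    n = calendar.n_points
    tol = 1e-9 * params.B
    best = (np.inf, None)
    for k in range(len(decisions) + 1):
        for combo in itertools.combinations(decisions, k):
            if any(b - a < calendar.dwell for a, b in zip(combo, combo[1:])):
                continue
            sched = ep.Schedule.from_indices(combo, n, v_max=v_max)
            traj = ep.simulate(
                params, ep.healthy_steady_state(params),
                float(calendar.horizon_days), dt=dt, schedule=sched,
            )
            if traj.x3.max() > bounds.x3_up + tol or traj.x3.min() < bounds.x3_lo - tol:
                continue
            # deviation checked at segment ends (decision arrivals and the
            # horizon end); a treatment and its own segment's mass cancel
            chosen = set(combo)
            sigma = float(u[: decisions[0]].sum() * dt)
            maxdev = abs(sigma)
            for k, d in enumerate(decisions):
                stop = decisions[k + 1] if k + 1 < len(decisions) else n
                if d in chosen:
                    sigma -= 1.0
                sigma += u[d:stop].sum() * dt
                maxdev = max(maxdev, abs(sigma))
            if maxdev < best[0] - 1e-12:
                best = (maxdev, combo)
    return best


class TestBnBRounding:
    def test_binary_feasible_control_returned_unchanged(self, patient20, bounds20):
        # daily-slot calendar; relaxed control concentrating one full
        # withdrawal day on each day the heuristic would bleed
        cal = ep.build_weekday_calendar(
            ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"], 103
        )
        h = ep.heuristic_schedule(patient20, cal, bounds20)
        assert h.feasible
        u = np.zeros(cal.n_points)
        for i in h.schedule.treatment_indices:
            u[i:i + 6] = 1.0
        sol = RelaxedSolution(ep.RelaxedControl(u), h.trajectory, float(u.sum()) / 6, cal.dt)
        res = ep.bnb_rounding(sol, patient20, cal, bounds20)
        assert res.status == "optimal"
        assert res.cost == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_array_equal(
            res.schedule.treatment_indices, h.schedule.treatment_indices
        )

    def test_matches_bruteforce_on_small_instance(self, patient20, bounds20):
        cal = ep.build_weekday_calendar(["Mon"], 84)  # 12 allowed Mondays
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 84.0)
        res = ep.bnb_rounding(sol, patient20, cal, bounds20)
        oracle_cost, oracle_combo = bnb_oracle(sol, patient20, cal, bounds20)
        assert res.status == "optimal"
        assert res.cost == pytest.approx(oracle_cost, abs=1e-9)

    def test_returned_schedule_is_feasible_on_resimulation(self, patient20, bounds20):
        cal = ep.build_weekday_calendar(["Mon", "Thu"], 103)
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 103.0)
        res = ep.bnb_rounding(sol, patient20, cal, bounds20)
        assert res.schedule is not None
        m = ep.score_schedule(res.schedule, patient20, bounds20, cal)
        assert m.d_viol == 0.0 and m.d_viol_lower == 0.0

    def test_larger_budget_never_worse(self, patient20, bounds20):
        cal = ep.build_weekday_calendar(["Mon"], 103)
        sol = ep.relaxed_schedule_analytic(patient20, bounds20, 103.0)
        small = ep.bnb_rounding(sol, patient20, cal, bounds20, config=BnBConfig(max_iterations=40))
        large = ep.bnb_rounding(sol, patient20, cal, bounds20, config=BnBConfig(max_iterations=500_000))
        if small.schedule is not None:
            assert large.cost <= small.cost + 1e-12

    def test_relaxed_objective_lower_bounds_binary_withdrawal(self, cohort):
        # the continuous optimum withdraws no more volume than any feasible
        # binary schedule (treatments expressed in full-withdrawal days)
        checked = 0
        for s in cohort[:10]:
            p = s.params(s.lambdas[1])
            b = ep.SafetyBounds.default_for(s.B)
            cal = ep.build_unconstrained_calendar(103)
            h = ep.heuristic_schedule(p, cal, b)
            if not h.feasible or h.n_treatments == 0:
                continue
            sol = ep.relaxed_schedule_analytic(p, b, 103.0)
            assert sol.objective <= h.n_treatments + 1e-9
            checked += 1
        assert checked >= 5
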
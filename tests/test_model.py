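import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import erythroplan as ep
from erythroplan.exceptions import (
    DivergenceError,
    InvalidControlError,
    InvalidParameterError,
    ScheduleMismatchError,
)
from erythroplan.model import PatientParams, SystemState


def make_params(beta=1.0, gamma=0.5, B=800.0, v_pat=5500.0, lam=0.0, **kw):
    return PatientParams(beta=beta, gamma=gamma, B=B, v_pat=v_pat, lambda_pv=lam, **kw)


class TestFeedback:
    @pytest.mark.parametrize(
        "x3_factor, expected_factor",
        [(1.0, 0.0), (0.0, 1.0), (2.0, -1.0)],
    )
    def test_feedback_values(self, x3_factor, expected_factor):
        gamma, B = 0.73, 912.0
        assert ep.feedback(x3_factor * B, gamma, B) == pytest.approx(expected_factor * gamma)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(InvalidParameterError):
            ep.feedback(100.0, 0.5, 0.0)


class TestRhs:
    def test_healthy_steady_state_is_fixed_point(self):
        p = make_params()
        s = ep.healthy_steady_state(p)
        d = ep.rhs_pv(s, p)
        assert abs(d.x1) < 1e-12 and abs(d.x2) < 1e-12 and abs(d.x3) < 1e-12

    def test_reduces_to_healthy_model_at_lambda_zero(self):
        p = make_params(lam=0.0)
        s = SystemState(40.0, 30.0, 700.0)
        d = ep.rhs_pv(s, p)
        c = p.constants
        fb = ep.feedback(s.x3, p.gamma, p.B)
        assert d.x1 == pytest.approx(p.beta * (p.X0 - c.k1 * s.x1) + fb * s.x1)
        assert d.x2 == pytest.approx(p.beta * (c.k1 * s.x1 - c.k2 * s.x2))
        assert d.x3 == pytest.approx(p.beta * (c.k2 * s.x2 - c.alpha * s.x3))

    @pytest.mark.parametrize("lam", [0.2, 0.5, 0.85])
    def test_pv_fixed_point_residual(self, lam, subject01):
        p = subject01.params(lam)
        s = ep.pv_steady_state_point(p)
        d = ep.rhs_pv(s, p)
        scale = max(abs(s.x1), abs(s.x3))
        assert max(abs(d.x1), abs(d.x2), abs(d.x3)) < 1e-9 * scale

    def test_control_outside_unit_interval_rejected(self):
        p = make_params()
        with pytest.raises(InvalidControlError):
            ep.rhs_pv(ep.healthy_steady_state(p), p, u=1.5)


class TestPhlebotomy:
    def test_fractional_removal(self):
        s = SystemState(1.0, 1.0, 1000.0)
        out = ep.apply_phlebotomy(s, u=1.0, v_max=500.0, v_pat=5000.0)
        assert out.x3 == pytest.approx(900.0)
        assert out.x1 == s.x1 and out.x2 == s.x2

    def test_no_treatment_is_identity(self):
        s = SystemState(1.0, 1.0, 1000.0)
        out = ep.apply_phlebotomy(s, u=0.0, v_max=500.0, v_pat=5000.0)
        assert out.x3 == s.x3

    def test_consecutive_treatments_compose_multiplicatively(self):
        s = SystemState(1.0, 1.0, 1000.0)
        f = 1.0 - 500.0 / 5000.0
        out = ep.apply_phlebotomy(
            ep.apply_phlebotomy(s, 1.0, 500.0, 5000.0), 1.0, 500.0, 5000.0
        )
        assert out.x3 == pytest.approx(1000.0 * f * f)

    def test_volume_exceeding_blood_volume_rejected(self):
        with pytest.raises(InvalidParameterError):
            ep.apply_phlebotomy(SystemState(1, 1, 1000.0), 1.0, 5000.0, 5000.0)


class TestSteadyStates:
    def test_healthy_components(self):
        p = make_params(B=865.45)
        s = ep.healthy_steady_state(p)
        c = p.constants
        assert s.x1 == pytest.approx(c.alpha * 865.45 / c.k1)
        assert s.x2 == pytest.approx(c.alpha * 865.45 / c.k2)
        assert s.x3 == 865.45

    def test_linear_in_base_value(self):
        a, b = ep.healthy_steady_state(make_params(B=500.0)), ep.healthy_steady_state(
            make_params(B=1500.0)
        )
        assert b.x1 == pytest.approx(3 * a.x1) and b.x3 == pytest.approx(3 * a.x3)

    def test_bpv_equals_base_at_lambda_zero(self):
        p = make_params()
        assert ep.pv_steady_state(p, 0.0) == pytest.approx(p.B)

    @pytest.mark.parametrize("beta", [0.424, 1.65, 3.142])
    def test_fivefold_amplification_at_full_burden(self, beta):
        # gamma* = beta/10 and k1 = 1/8 give B_PV(1) = 5 B regardless of beta, B
        p = make_params(beta=beta)
        assert ep.pv_steady_state(p, 1.0) == pytest.approx(5.0 * p.B, rel=1e-12)

    @pytest.mark.parametrize(
        "beta, gamma, lam, B, expected, rtol",
        [
            (0.2, 0.1, 0.62, 501.04, 607.02, 2e-4),   # clinical patient 02
            (0.2, 0.1, 0.61, 540.17, 650.21, 1e-3),   # clinical patient 03
        ],
    )
    def test_printed_clinical_fits(self, beta, gamma, lam, B, expected, rtol):
        p = make_params(beta=beta, gamma=gamma, B=B, lam=lam)
        assert ep.pv_steady_state(p) == pytest.approx(expected, rel=rtol)

    def test_divergence_when_affected_growth_exceeds_turnover(self):
        p = make_params(beta=1.0, gamma_star=0.2)  # beta*k1 = 0.125 < 0.2
        with pytest.raises(DivergenceError):
            ep.pv_steady_state(p, 1.0)

    def test_continuity_at_full_burden(self, subject01):
        p = subject01.params(1.0)
        assert abs(ep.pv_steady_state(p, 1.0 - 1e-6) - ep.pv_steady_state(p, 1.0)) < 1e-3 * p.B

    def test_monotone_in_burden(self, subject02):
        lams = np.linspace(0, 1, 101)
        vals = [ep.pv_steady_state(subject02.params(0.0), l) for l in lams]
        assert np.all(np.diff(vals) >= -1e-9)

    @given(
        beta=st.floats(0.05, 4.0),
        gamma=st.floats(0.05, 1.2),
        lam=st.floats(0.0, 1.0),
        B=st.floats(300.0, 1500.0),
    )
    def test_amplification_bounded(self, beta, gamma, lam, B):
        p = make_params(beta=beta, gamma=gamma, B=B, lam=0.0)
        v = ep.pv_steady_state(p, lam)
        assert B * (1 - 1e-12) <= v <= 5 * B * (1 + 1e-12)

    def test_agrees_with_long_simulation(self, subject02):
        p = subject02.params(0.45)
        bpv = ep.pv_steady_state(p)
        traj = ep.simulate(p, ep.healthy_steady_state(p), 5000.0, dt=0.5)
        assert traj.x3[-1] == pytest.approx(bpv, rel=1e-3)


class TestSimulate:
    def test_fixed_point_invariance(self):
        p = make_params()
        s = ep.healthy_steady_state(p)
        traj = ep.simulate(p, s, 60.0)
        assert np.all(np.abs(traj.x3 - p.B) <= 1e-6 * p.B)

    def test_convergence_to_pv_steady_state(self, subject01):
        # untreated disease: x3 converges to B_PV (damped oscillation with
        # at most a small overshoot, here ~0.14%)
        p = subject01.params(0.4)
        traj = ep.simulate(p, ep.healthy_steady_state(p), 600.0, dt=0.5)
        bpv = ep.pv_steady_state(p)
        assert traj.x3[-1] == pytest.approx(bpv, rel=1e-6)
        assert traj.x3.max() <= bpv * 1.005
        assert traj.x3.min() >= p.B * (1 - 1e-9)

    def test_rk4_convergence_order(self, subject01):
        p = subject01.params(0.5)
        x0 = ep.healthy_steady_state(p)
        ref = ep.simulate(p, x0, 10.0, dt=0.005).x3[-1]
        e1 = abs(ep.simulate(p, x0, 10.0, dt=0.5).x3[-1] - ref)
        e2 = abs(ep.simulate(p, x0, 10.0, dt=0.25).x3[-1] - ref)
        order = math.log2(e1 / e2)
        assert order >= 3.8

    def test_schedule_events_applied_after_step(self):
        p = make_params()
        x0 = ep.healthy_steady_state(p)
        n = round(10.0 / ep.DEFAULT_DT)
        U = np.zeros(n + 1)
        U[12] = 1
        traj = ep.simulate(p, x0, 10.0, schedule=U)
        free = ep.simulate(p, x0, 10.0)
        f = 1.0 - 500.0 / p.v_pat
        assert traj.x3[12] == pytest.approx(free.x3[12] * f)
        assert traj.x3[11] == pytest.approx(free.x3[11])

    def test_mismatched_schedule_rejected(self):
        p = make_params()
        with pytest.raises(ScheduleMismatchError):
            ep.simulate(p, ep.healthy_steady_state(p), 10.0, schedule=np.zeros(5))

    @given(st.integers(0, 2**31 - 1))
    def test_positivity_under_random_schedules(self, seed):
        rng = np.random.default_rng(seed)
        p = make_params(lam=float(rng.uniform(0, 0.9)))
        n = round(30.0 / ep.DEFAULT_DT)
        U = np.zeros(n + 1)
        days = rng.choice(np.arange(1, 30), size=4, replace=False)
        U[days * 6] = 1
        traj = ep.simulate(p, ep.healthy_steady_state(p), 30.0, schedule=U)
        assert np.all(traj.states > 0)


class TestSerialization:
    def test_patient_json_round_trip(self, subject02):
        p = subject02.params(0.5)
        q = PatientParams.from_json(p.to_json())
        assert q == p

    def test_trajectory_csv_round_trip(self, tmp_path, subject02):
        p = subject02.params(0.3)
        traj = ep.simulate(p, ep.healthy_steady_state(p), 10.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = ep.Trajectory.from_csv(path)
        np.testing.assert_allclose(back.states, traj.states)
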
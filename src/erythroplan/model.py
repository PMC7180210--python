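"""Three-compartment erythropoiesis model with a polycythemia-vera extension.

The healthy model tracks two bone-marrow precursor pools ``x1`` (CFU-E and
early erythroblasts, strongly EPO-responsive) and ``x2`` (late erythroblasts
and reticulocytes), feeding the circulating erythrocyte mass ``x3`` [g].
Erythropoietin is represented indirectly through the negative feedback
``Fb(x3) = gamma * (1 - x3 / B)`` acting on the proliferation of ``x1``,
where ``B`` is the subject's healthy steady-state erythrocyte mass.

Polycythemia vera is modelled by splitting the CFU-E pool: a fraction
``lambda_pv`` of cells proliferates at a fixed rate ``gamma_star``
independently of EPO, while the remaining ``1 - lambda_pv`` keeps the healthy
feedback.  A phlebotomy withdraws ``v_max`` ml out of the patient's total
blood volume ``v_pat`` and therefore removes the fraction ``v_max / v_pat``
of the circulating mass ``x3``; precursors in the marrow are unaffected.

All computation is carried out numerically in (day, gram, ml).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DivergenceError,
    InvalidControlError,
    InvalidParameterError,
    ScheduleMismatchError,
)

__all__ = [
    "ModelConstants",
    "PatientParams",
    "SystemState",
    "Trajectory",
    "DEFAULT_DT",
    "DEFAULT_V_MAX",
    "feedback",
    "rhs_pv",
    "apply_phlebotomy",
    "healthy_steady_state",
    "pv_steady_state",
    "pv_steady_state_point",
    "simulate",
]

#: Default integrator step [day].
DEFAULT_DT = 1.0 / 6.0
#: Standard phlebotomy volume [ml].
DEFAULT_V_MAX = 500.0


@dataclass(frozen=True)
class ModelConstants:
    """Literature transition/clearance rates shared by all subjects.

    ``k1`` and ``k2`` [1/day] are the maturation rates out of the two
    precursor compartments; ``alpha`` [1/day] is the erythrocyte clearance
    rate, the reciprocal of the ~120-day red-cell lifespan.  The stem-cell
    inflow is ``X0 = alpha * B`` and therefore lives on the patient record.
    """

    k1: float = 1.0 / 8.0
    k2: float = 1.0 / 6.0
    alpha: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.alpha > 0):
            raise InvalidParameterError("k1, k2 and alpha must be positive")


@dataclass(frozen=True)
class PatientParams:
    """One subject's model parameters.

    Parameters
    ----------
    beta : float
        EPO-independent proliferation factor [1].
    gamma : float
        EPO-dependent proliferation factor [1/day].
    B : float
        Healthy steady-state erythrocyte mass [g].
    v_pat : float
        Total blood volume [ml].
    lambda_pv : float
        Fraction of PV-affected CFU-E cells, in [0, 1]; 0 means healthy.
    gamma_star : float, optional
        Growth rate of the affected cells [1/day]; defaults to ``beta / 10``.
    """

    beta: float
    gamma: float
    B: float
    v_pat: float
    lambda_pv: float = 0.0
    gamma_star: Optional[float] = None
    constants: ModelConstants = field(default_factory=ModelConstants)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.gamma > 0 and self.B > 0 and self.v_pat > 0):
            raise InvalidParameterError("beta, gamma, B and v_pat must be positive")
        if not 0.0 <= self.lambda_pv <= 1.0:
            raise InvalidParameterError("lambda_pv must lie in [0, 1]")
        if self.gamma_star is None:
            object.__setattr__(self, "gamma_star", self.beta / 10.0)
        elif self.gamma_star <= 0:
            raise InvalidParameterError("gamma_star must be positive")

    @property
    def X0(self) -> float:
        """Stem-cell inflow [1/day], defined as ``alpha * B``."""
        return self.constants.alpha * self.B

    def with_lambda(self, lambda_pv: float) -> "PatientParams":
        """Copy of this record with a different affected-cell fraction."""
        return PatientParams(
            beta=self.beta,
            gamma=self.gamma,
            B=self.B,
            v_pat=self.v_pat,
            lambda_pv=lambda_pv,
            gamma_star=self.gamma_star,
            constants=self.constants,
            subject_id=self.subject_id,
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.subject_id,
            "gamma": self.gamma,
            "beta": self.beta,
            "B": self.B,
            "V_pat": self.v_pat,
            "lambda_pv": self.lambda_pv,
            "gamma_star": self.gamma_star,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PatientParams":
        return cls(
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
            B=float(d["B"]),
            v_pat=float(d["V_pat"]),
            lambda_pv=float(d.get("lambda_pv", 0.0)),
            gamma_star=(None if d.get("gamma_star") in (None, "") else float(d["gamma_star"])),
            subject_id=str(d.get("id", "")),
        )

    @classmethod
    def from_json(cls, s: str) -> "PatientParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class SystemState:
    """The three compartments at one time point."""

    x1: float
    x2: float
    x3: float
    t: float = 0.0

    def as_tuple(self) -> tuple:
        return (self.x1, self.x2, self.x3)


class Trajectory:
    """States on an equidistant time grid.

    ``times`` has shape (N+1,), ``states`` has shape (N+1, 3) with columns
    (x1, x2, x3).  When binary treatments were simulated, the stored state at
    a treatment index is the post-withdrawal state.
    """

    def __init__(self, times: np.ndarray, states: np.ndarray):
        times = np.asarray(times, dtype=float)
        states = np.asarray(states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 3):
            raise ValueError("times must be (N+1,), states (N+1, 3)")
        if times.size >= 2:
            steps = np.diff(times)
            if not np.all(steps > 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must be strictly increasing and equidistant")
        self.times = times
        self.states = states

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]

    def state_at(self, i: int) -> SystemState:
        return SystemState(*self.states[i], t=float(self.times[i]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x1": self.x1, "x2": self.x2, "x3": self.x3}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df[["x1", "x2", "x3"]].to_numpy())

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def feedback(x3: float, gamma: float, B: float) -> float:
    """EPO-mediated feedback ``gamma * (1 - x3 / B)``.

    Negative for ``x3 > B``: an erythrocyte surplus suppresses proliferation.
    """
    if B <= 0:
        raise InvalidParameterError("B must be positive")
    return gamma * (1.0 - x3 / B)


def _rhs(x1: float, x2: float, x3: float, p: PatientParams, uc: float) -> tuple:
    """Scalar right-hand side; ``uc = u * v_max / v_pat`` [1/day]."""
    c = p.constants
    lam = p.lambda_pv
    fb = p.gamma * (1.0 - x3 / p.B)
    dx1 = p.beta * (p.X0 - c.k1 * x1) + ((1.0 - lam) * fb + lam * p.gamma_star) * x1
    dx2 = p.beta * (c.k1 * x1 - c.k2 * x2)
    dx3 = p.beta * (c.k2 * x2 - c.alpha * x3) - uc * x3
    return dx1, dx2, dx3


def rhs_pv(
    state: SystemState,
    params: PatientParams,
    u: float = 0.0,
    v_max: float = DEFAULT_V_MAX,
) -> SystemState:
    """Time derivative of the PV model with continuous fractional withdrawal.

    ``u`` in [0, 1] scales the maximal continuous withdrawal rate
    ``v_max / v_pat * x3`` entering the erythrocyte equation.
    """
    if not 0.0 <= u <= 1.0:
        raise InvalidControlError(f"u={u} outside [0, 1]")
    dx1, dx2, dx3 = _rhs(state.x1, state.x2, state.x3, params, u * v_max / params.v_pat)
    return SystemState(dx1, dx2, dx3, t=state.t)


def apply_phlebotomy(
    state: SystemState,
    u: float = 1.0,
    v_max: float = DEFAULT_V_MAX,
    v_pat: float = None,
) -> SystemState:
    """Instantaneous withdrawal: scale ``x3`` by ``1 - u * v_max / v_pat``.

    Precursors ``x1``/``x2`` sit in the bone marrow and are untouched by
    venesection.
    """
    if v_pat is None:
        raise InvalidParameterError("v_pat is required")
    if not 0.0 <= u <= 1.0:
        raise InvalidControlError(f"u={u} outside [0, 1]")
    if v_max >= v_pat:
        raise InvalidParameterError("v_max must be smaller than v_pat")
    return SystemState(state.x1, state.x2, state.x3 * (1.0 - u * v_max / v_pat), t=state.t)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def healthy_steady_state(params: PatientParams) -> SystemState:
    """Unique positive fixed point of the healthy model: (aB/k1, aB/k2, B)."""
    c = params.constants
    aB = c.alpha * params.B
    return SystemState(aB / c.k1, aB / c.k2, params.B, t=0.0)


def pv_steady_state(params: PatientParams, lambda_pv: Optional[float] = None) -> float:
    """Steady-state erythrocyte mass ``B_PV`` [g] of the PV-extended model.

    For ``lambda_pv < 1`` the ratio ``r = B_PV / B`` is the positive root of

        (1 - lam) * gamma * r**2
            + (beta*k1 - (1 - lam)*gamma - lam*gamma_star) * r - beta*k1 = 0,

    obtained by zeroing the dynamics at ``x1 = alpha x3 / k1``,
    ``x2 = alpha x3 / k2``.  For ``lambda_pv = 1`` the feedback is fully
    bypassed and ``r = beta*k1 / (beta*k1 - gamma_star)``, which requires
    ``beta*k1 > gamma_star`` — otherwise the affected pool grows without
    bound and no steady state exists.

    The function is continuous and non-decreasing on [0, 1] and equals ``B``
    at 0; with the default ``gamma_star = beta/10`` and ``k1 = 1/8`` it is
    confined to [B, 5B].
    """
    lam = params.lambda_pv if lambda_pv is None else float(lambda_pv)
    if not 0.0 <= lam <= 1.0:
        raise InvalidParameterError("lambda_pv must lie in [0, 1]")
    c = params.constants
    bk1 = params.beta * c.k1
    if lam == 1.0:
        if bk1 <= params.gamma_star:
            raise DivergenceError(
                "no steady state at lambda_pv=1: beta*k1 <= gamma_star"
            )
        return params.B * bk1 / (bk1 - params.gamma_star)
    g = (1.0 - lam) * params.gamma
    q = (bk1 - g - lam * params.gamma_star) / (2.0 * g)
    d = bk1 / g
    if q > 0.0:
        # algebraically identical, numerically stable for q -> +inf (lam -> 1)
        r = d / (q + math.sqrt(q * q + d))
    else:
        r = -q + math.sqrt(q * q + d)
    return params.B * r


def pv_steady_state_point(params: PatientParams) -> SystemState:
    """Full fixed-point state at the patient's own ``lambda_pv``."""
    bpv = pv_steady_state(params)
    c = params.constants
    return SystemState(c.alpha * bpv / c.k1, c.alpha * bpv / c.k2, bpv, t=0.0)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _rk4_step(x1, x2, x3, p: PatientParams, uc: float, dt: float):
    a1, b1, c1 = _rhs(x1, x2, x3, p, uc)
    h = 0.5 * dt
    a2, b2, c2 = _rhs(x1 + h * a1, x2 + h * b1, x3 + h * c1, p, uc)
    a3, b3, c3 = _rhs(x1 + h * a2, x2 + h * b2, x3 + h * c2, p, uc)
    a4, b4, c4 = _rhs(x1 + dt * a3, x2 + dt * b3, x3 + dt * c3, p, uc)
    s = dt / 6.0
    return (
        x1 + s * (a1 + 2.0 * (a2 + a3) + a4),
        x2 + s * (b1 + 2.0 * (b2 + b3) + b4),
        x3 + s * (c1 + 2.0 * (c2 + c3) + c4),
    )


def simulate(
    params: PatientParams,
    x0: SystemState,
    horizon: float,
    dt: float = DEFAULT_DT,
    schedule=None,
    control: Optional[Sequence[float]] = None,
    v_max: float = DEFAULT_V_MAX,
) -> Trajectory:
    """Integrate the PV model with classic fixed-step RK4.

    Parameters
    ----------
    horizon : float
        Final time [day]; must be an integer multiple of ``dt``.
    schedule : Schedule or array-like of 0/1, optional
        Binary treatment indicators per grid index (length N+1).  A
        treatment at index ``i > 0`` is applied as an instantaneous
        multiplicative withdrawal *after* the integration step arriving at
        ``i``; an indicator at index 0 scales the initial state.
    control : array-like, optional
        Fractional withdrawal in [0, 1], one value per grid *interval*
        (length N), entering the dynamics continuously.  Mutually exclusive
        with ``schedule``.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    n_steps = round(horizon / dt)
    if abs(n_steps * dt - horizon) > 1e-9 * max(1.0, horizon):
        raise InvalidParameterError("horizon must be a multiple of dt")
    if schedule is not None and control is not None:
        raise ScheduleMismatchError("give either a binary schedule or a relaxed control")

    indicators = None
    if schedule is not None:
        indicators = np.asarray(getattr(schedule, "U", schedule), dtype=float)
        sv = getattr(schedule, "v_max", None)
        if sv is not None:
            v_max = float(sv)
        if indicators.size != n_steps + 1:
            raise ScheduleMismatchError(
                f"schedule has {indicators.size} indicators, grid has {n_steps + 1} points"
            )
    u_arr = None
    if control is not None:
        u_arr = np.asarray(control, dtype=float)
        if u_arr.size != n_steps:
            raise ScheduleMismatchError(
                f"control has {u_arr.size} values, grid has {n_steps} intervals"
            )
        if u_arr.min() < -1e-12 or u_arr.max() > 1.0 + 1e-12:
            raise InvalidControlError("control values must lie in [0, 1]")

    frac = v_max / params.v_pat
    if frac >= 1.0:
        raise InvalidParameterError("v_max must be smaller than v_pat")
    cmax = v_max / params.v_pat  # withdrawal rate scale [1/day]

    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 3))
    x1, x2, x3 = x0.x1, x0.x2, x0.x3
    if indicators is not None and indicators[0]:
        x3 *= 1.0 - frac
    out[0] = (x1, x2, x3)
    for i in range(n_steps):
        uc = cmax * u_arr[i] if u_arr is not None else 0.0
        x1, x2, x3 = _rk4_step(x1, x2, x3, params, uc, dt)
        if indicators is not None and indicators[i + 1]:
            x3 *= 1.0 - frac
        out[i + 1] = (x1, x2, x3)
    return Trajectory(times, out)


def simulate_feedback_control(
    params: PatientParams,
    x0: SystemState,
    horizon: float,
    law: Callable[[float, float, float], float],
    dt: float = DEFAULT_DT,
    v_max: float = DEFAULT_V_MAX,
):
    """Integrate with a state-feedback control ``u = law(x1, x2, x3)``.

    The law is evaluated once per step at the interval's left endpoint and
    held constant across the RK4 stages.  Returns ``(Trajectory, u_applied)``
    with one control value per interval.
    """
    n_steps = round(horizon / dt)
    if abs(n_steps * dt - horizon) > 1e-9 * max(1.0, horizon):
        raise InvalidParameterError("horizon must be a multiple of dt")
    cmax = v_max / params.v_pat
    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 3))
    u_out = np.empty(n_steps)
    x1, x2, x3 = x0.x1, x0.x2, x0.x3
    out[0] = (x1, x2, x3)
    for i in range(n_steps):
        u = law(x1, x2, x3)
        if not 0.0 <= u <= 1.0:
            raise InvalidControlError(f"feedback law returned u={u}")
        u_out[i] = u
        x1, x2, x3 = _rk4_step(x1, x2, x3, params, cmax * u, dt)
        out[i + 1] = (x1, x2, x3)
    return Trajectory(times, out), u_out
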
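"""Patient-specific parameter estimation from total-hemoglobin series.

``TotalHbModel`` is a data-bound model object in the statsmodels mould: it
is constructed from a measurement series (and the known phlebotomy dates,
if any), and ``fit()`` returns a ``TotalHbResults`` carrying the estimates,
the objective, a goodness-of-fit R², and a ``summary()`` table.

The objective is regularized weighted least squares,

    1/2 * sum_i (eta_i - x3(t_i))^2 / sigma_i^2
        + sum_j ((p_j - p_j^prior) / p_j^prior)^2,

over the parameter vector p = (beta, gamma, lambda_pv, x1_0, x2_0).  The
simulation starts at x(0) = (x1_0, x2_0, eta_0): the first measurement
anchors the observable state, while the unobservable precursor levels are
estimated.  The healthy base value B is not fitted; it is the average of
the tHb measurements taken at hematocrit <= 45%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import EstimationError, InvalidParameterError
from .model import DEFAULT_V_MAX, ModelConstants, PatientParams, SystemState, simulate

__all__ = [
    "MeasurementSeries",
    "TotalHbModel",
    "TotalHbResults",
    "estimate_base_value",
    "PARAM_NAMES",
]

PARAM_NAMES = ("beta", "gamma", "lambda_pv", "x1_0", "x2_0")

#: Lower bound on beta and gamma; fits pinned here signal degenerate data.
EPS_B = 0.05


@dataclass(frozen=True)
class MeasurementSeries:
    """tHb observations: strictly increasing times [day], values [g],
    per-point standard deviations (default 1 g for all points)."""

    times: np.ndarray
    values: np.ndarray
    sigmas: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = (
            np.ones_like(t)
            if self.sigmas is None
            else np.asarray(self.sigmas, dtype=float)
        )
        if t.ndim != 1 or t.size != v.size or t.size != s.size:
            raise InvalidParameterError("times, values and sigmas must align")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing (>= 2 points)")
        if np.any(s <= 0):
            raise InvalidParameterError("sigmas must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sigmas", s)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MeasurementSeries":
        return cls(
            df["t"].to_numpy(),
            df["thb"].to_numpy(),
            df["sigma"].to_numpy() if "sigma" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "MeasurementSeries":
        return cls.from_dataframe(pd.read_csv(path))


def estimate_base_value(thb: Sequence[float], hct: Sequence[float]) -> float:
    """Healthy base value B: mean tHb over samples with Hct <= 45%."""
    thb = np.asarray(thb, dtype=float)
    hct = np.asarray(hct, dtype=float)
    if thb.size != hct.size:
        raise InvalidParameterError("thb and hct must align")
    mask = hct <= 0.45
    if not mask.any():
        raise EstimationError("no measurement with Hct <= 45%; B cannot be estimated")
    return float(thb[mask].mean())


class TotalHbModel:
    """Regularized least-squares fit of the PV model to a tHb series.

    Parameters
    ----------
    series : MeasurementSeries
        Observations; the first time point defines t = 0 internally.
    B : float
        Healthy base value [g] (see :func:`estimate_base_value`).
    v_pat : float
        Total blood volume [ml].
    priors : dict, optional
        Prior values for (beta, gamma, lambda_pv, x1_0, x2_0); the
        regularization pulls towards them.  Defaults: healthy-cohort
        medians for beta/gamma, 0.5 for lambda_pv, and the healthy
        steady-state precursor levels implied by B.
    treatment_times : sequence of float, optional
        Known phlebotomy days within the series; each removes
        ``v_max / v_pat`` of x3 in the fitting simulation.
    dt : float
        Simulation step used during fitting [day].
    """

    #: cohort medians of the packaged healthy subjects (fallback priors)
    _DEFAULT_BETA = 1.5
    _DEFAULT_GAMMA = 0.45

    def __init__(
        self,
        series: MeasurementSeries,
        B: float,
        v_pat: float,
        priors: Optional[Dict[str, float]] = None,
        treatment_times: Sequence[float] = (),
        v_max: float = DEFAULT_V_MAX,
        gamma_star: Optional[float] = None,
        dt: float = 0.5,
        constants: Optional[ModelConstants] = None,
    ):
        self.series = series
        self.B = float(B)
        self.v_pat = float(v_pat)
        self.v_max = float(v_max)
        self.gamma_star = gamma_star
        self.dt = float(dt)
        self.constants = constants or ModelConstants()
        c = self.constants
        defaults = {
            "beta": self._DEFAULT_BETA,
            "gamma": self._DEFAULT_GAMMA,
            "lambda_pv": 0.5,
            "x1_0": c.alpha * self.B / c.k1,
            "x2_0": c.alpha * self.B / c.k2,
        }
        if priors:
            defaults.update(priors)
        self.priors = defaults

        t0 = series.times[0]
        self._rel_times = series.times - t0
        self._horizon = float(np.ceil(self._rel_times[-1] / self.dt)) * self.dt
        n = round(self._horizon / self.dt)
        self._U = np.zeros(n + 1, dtype=np.int8)
        for tt in treatment_times:
            # snap to the next grid point: a withdrawal must never move
            # ahead of a measurement taken just before it
            i = int(np.ceil((tt - t0) / self.dt - 1e-9))
            if not 0 <= i <= n:
                raise InvalidParameterError(f"treatment time {tt} outside the series span")
            self._U[i] = 1

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, B: Optional[float] = None, v_pat: float = 5500.0, **kw
    ) -> "TotalHbModel":
        """Build from a (t, thb[, sigma][, hct]) frame; B from Hct <= 45%
        rows when not supplied."""
        series = MeasurementSeries.from_dataframe(df)
        if B is None:
            if "hct" not in df:
                raise EstimationError("supply B or include an hct column")
            B = estimate_base_value(df["thb"].to_numpy(), df["hct"].to_numpy())
        return cls(series, B=B, v_pat=v_pat, **kw)

    # -- objective --------------------------------------------------------

    def _params_from_vector(self, p: np.ndarray) -> PatientParams:
        return PatientParams(
            beta=float(p[0]), gamma=float(p[1]), B=self.B, v_pat=self.v_pat,
            lambda_pv=float(min(max(p[2], 0.0), 1.0)),
            gamma_star=self.gamma_star, constants=self.constants,
        )

    def _predict_x3(self, p: np.ndarray) -> np.ndarray:
        params = self._params_from_vector(p)
        x0 = SystemState(float(p[3]), float(p[4]), float(self.series.values[0]))
        traj = simulate(
            params, x0, self._horizon, dt=self.dt, schedule=self._U, v_max=self.v_max
        )
        return np.interp(self._rel_times, traj.times, traj.x3)

    def regularization(self, p: np.ndarray) -> float:
        prior = np.array([self.priors[k] for k in PARAM_NAMES])
        return float(np.sum(((p - prior) / prior) ** 2))

    def objective(self, p: np.ndarray) -> float:
        """Weighted least squares plus prior regularization; non-finite
        simulations yield ``inf`` (flagged, not raised)."""
        p = np.asarray(p, dtype=float)
        try:
            x3 = self._predict_x3(p)
        except (OverflowError, FloatingPointError):
            return np.inf
        if not np.all(np.isfinite(x3)):
            return np.inf
        r = (self.series.values - x3) / self.series.sigmas
        return 0.5 * float(r @ r) + self.regularization(p)

    # -- fitting ----------------------------------------------------------

    def default_bounds(self) -> Tuple[Tuple[float, float], ...]:
        return (
            (EPS_B, 10.0),                 # beta
            (EPS_B, 10.0),                 # gamma
            (0.0, 1.0),                    # lambda_pv
            (0.1 * self.priors["x1_0"], 10.0 * self.priors["x1_0"]),
            (0.1 * self.priors["x2_0"], 10.0 * self.priors["x2_0"]),
        )

    def fit(
        self,
        multistart: int = 5,
        seed: int = 0,
        bounds: Optional[Tuple[Tuple[float, float], ...]] = None,
        maxiter: int = 200,
    ) -> "TotalHbResults":
        """Bound-constrained local minimization with seeded multistarts.

        The first start is the prior vector itself; the remaining starts
        perturb it (log-normal 20% on positive parameters, uniform jitter
        on lambda_pv), all clipped to the bounds.
        """
        if bounds is None:
            bounds = self.default_bounds()
        rng = np.random.default_rng(seed)
        p_prior = np.array([self.priors[k] for k in PARAM_NAMES])
        starts = [p_prior]
        for _ in range(max(0, multistart - 1)):
            p = p_prior.copy()
            jitter = np.exp(rng.normal(0.0, 0.2, size=5))
            p = p * jitter
            p[2] = np.clip(p_prior[2] + rng.uniform(-0.2, 0.2), 0.0, 1.0)
            starts.append(np.clip(p, [b[0] for b in bounds], [b[1] for b in bounds]))

        # optimize in prior units so the finite-difference steps are
        # commensurate across parameters; blow-ups get a finite penalty so
        # the line search can back off instead of choking on inf
        scale = p_prior.copy()
        scale[2] = 1.0

        def obj_scaled(z):
            v = self.objective(z * scale)
            return v if np.isfinite(v) else 1e12

        bounds_z = [(lo / s, hi / s) for (lo, hi), s in zip(bounds, scale)]
        best = None
        best_x = None
        n_failed = 0
        for p0 in starts:
            try:
                res = minimize(
                    obj_scaled, p0 / scale, method="L-BFGS-B", bounds=bounds_z,
                    options={"maxiter": maxiter},
                )
            except Exception:
                n_failed += 1
                continue
            if not np.isfinite(res.fun) or res.fun >= 1e12:
                n_failed += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
                best_x = res.x * scale
        if best is None:
            raise EstimationError(
                f"all {len(starts)} starts failed (n_failed={n_failed})"
            )
        x3_hat = self._predict_x3(best_x)
        y = self.series.values
        ss_res = float(np.sum((y - x3_hat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return TotalHbResults(
            model=self,
            params=dict(zip(PARAM_NAMES, map(float, best_x))),
            objective=float(best.fun),
            r_squared=r2,
            fitted=x3_hat,
            converged=bool(best.success),
            n_starts=len(starts),
            seed=seed,
            bounds=tuple(bounds),
        )


@dataclass
class TotalHbResults:
    """Fit outcome: point estimates, objective, and goodness of fit."""

    model: TotalHbModel
    params: Dict[str, float]
    objective: float
    r_squared: float
    fitted: np.ndarray
    converged: bool
    n_starts: int
    seed: int
    bounds: Tuple[Tuple[float, float], ...]

    @property
    def patient_params(self) -> PatientParams:
        p = self.params
        return PatientParams(
            beta=p["beta"], gamma=p["gamma"], B=self.model.B,
            v_pat=self.model.v_pat, lambda_pv=p["lambda_pv"],
            gamma_star=self.model.gamma_star, constants=self.model.constants,
        )

    @property
    def b_pv(self) -> float:
        """Implied PV steady-state erythrocyte mass [g]."""
        from .model import pv_steady_state

        return pv_steady_state(self.patient_params)

    def summary(self) -> str:
        lines = [
            "TotalHbModel fit",
            "================",
            f"observations: {self.model.series.times.size}"
            f"   B = {self.model.B:.2f} g   V_pat = {self.model.v_pat:.0f} ml",
            f"objective: {self.objective:.4f}   R^2: {self.r_squared:.3f}"
            f"   converged: {self.converged}   starts: {self.n_starts}",
            "",
            f"{'param':>10} {'estimate':>12} {'prior':>12} {'lower':>10} {'upper':>10}",
        ]
        for k, (lo, hi) in zip(PARAM_NAMES, self.bounds):
            lines.append(
                f"{k:>10} {self.params[k]:>12.4f} {self.model.priors[k]:>12.4f} "
                f"{lo:>10.4f} {hi:>10.4f}"
            )
        lines.append("")
        lines.append(f"implied B_PV: {self.b_pv:.2f} g")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params,
                "priors": self.model.priors,
                "bounds": [list(b) for b in self.bounds],
                "objective": self.objective,
                "r_squared": self.r_squared,
                "converged": self.converged,
                "n_starts": self.n_starts,
                "seed": self.seed,
                "B": self.model.B,
                "b_pv": self.b_pv,
            }
        )
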
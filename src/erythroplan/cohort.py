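"""Reference cohort, tHb derivation from blood counts, and virtual patients.

The packaged fixture holds the 28 healthy-subject parameter sets
(gamma, beta, B, V_pat) together with the five published in-silico
PV fractions per subject — 140 (subject, lambda_PV) configurations in all.

Virtual PV patients are produced by rejection sampling: draw
``lambda_PV ~ Uniform(0, 1)``, run the unconstrained heuristic over a year,
and accept the draw when the implied number of phlebotomies lies in
[1, 26] — sick enough to need at least one bleed per year, but not so sick
that more than fortnightly bleeding (i.e. chemotherapy territory) would be
required.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calendars import SafetyBounds
from .exceptions import ErythroplanError, InvalidParameterError
from .heuristic import count_treatments_365
from .model import DEFAULT_DT, DEFAULT_V_MAX, PatientParams, simulate

__all__ = [
    "SubjectRecord",
    "BloodCountSample",
    "load_reference_cohort",
    "reference_cohort_frame",
    "nadler_volume",
    "thb_from_counts",
    "sample_pv_fraction",
    "generate_insilico_cohort",
    "synth_measurements",
]

ACCEPT_RANGE = (1, 26)          # accepted yearly treatment counts, inclusive
DEFAULT_DRAW_LIMIT = 10_000     # guard against non-terminating rejection loops


@dataclass(frozen=True)
class SubjectRecord:
    """One packaged subject: healthy parameters plus five accepted lambdas."""

    id: str
    gamma: float
    beta: float
    B: float
    v_pat: float
    lambdas: Tuple[float, ...]

    def params(self, lambda_pv: float = 0.0) -> PatientParams:
        return PatientParams(
            beta=self.beta, gamma=self.gamma, B=self.B, v_pat=self.v_pat,
            lambda_pv=lambda_pv, subject_id=self.id,
        )


@dataclass(frozen=True)
class BloodCountSample:
    """A routine blood count with the covariates needed for tHb."""

    time: float
    ery: float      # erythrocyte count [Tpt/l]
    mch: float      # mean corpuscular hemoglobin [pg]
    hct: float      # hematocrit, fraction in (0, 1)
    height: float   # [m]
    weight: float   # [kg]
    sex: str        # "male" | "female"

    def __post_init__(self) -> None:
        if self.ery <= 0 or self.mch <= 0:
            raise InvalidParameterError("ery and mch must be positive")
        if not 0 < self.hct < 1:
            raise InvalidParameterError("hct must be a fraction in (0, 1)")


def reference_cohort_frame() -> pd.DataFrame:
    """The packaged 28-subject table as a DataFrame."""
    with resources.files("erythroplan.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh, dtype={"id": str})


def load_reference_cohort() -> List[SubjectRecord]:
    """All 28 packaged subjects, each with its five published lambdas."""
    df = reference_cohort_frame()
    records = [
        SubjectRecord(
            id=row["id"],
            gamma=float(row["gamma"]),
            beta=float(row["beta"]),
            B=float(row["B"]),
            v_pat=float(row["V_pat"]),
            lambdas=tuple(float(row[f"lambda_{k}"]) for k in range(1, 6)),
        )
        for _, row in df.iterrows()
    ]
    if len(records) != 28 or any(len(r.lambdas) != 5 for r in records):
        raise ErythroplanError("packaged cohort fixture is corrupted")
    return records


# ---------------------------------------------------------------------------
# tHb from blood counts
# ---------------------------------------------------------------------------

# Nadler's regression coefficients for total blood volume [l] from
# height [m] and weight [kg].
_NADLER = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}


def nadler_volume(height: float, weight: float, sex: str) -> float:
    """Total blood volume [l]: ``a * h^3 + b * w + c`` with sex-specific
    coefficients."""
    if height <= 0 or weight <= 0:
        raise InvalidParameterError("height and weight must be positive")
    try:
        a, b, c = _NADLER[sex.lower()]
    except (KeyError, AttributeError):
        raise InvalidParameterError(f"unknown sex code {sex!r}") from None
    return a * height**3 + b * weight + c


def thb_from_counts(sample: BloodCountSample) -> float:
    """Total hemoglobin mass [g] = Ery [Tpt/l] * MCH [pg] * volume [l].

    1 Tpt/l * 1 pg = 1 g/l, so the product with the Nadler volume is grams.
    """
    return sample.ery * sample.mch * nadler_volume(sample.height, sample.weight, sample.sex)


# ---------------------------------------------------------------------------
# rejection sampling of PV fractions
# ---------------------------------------------------------------------------

def sample_pv_fraction(
    subject: SubjectRecord,
    bounds: Optional[SafetyBounds] = None,
    seed: Optional[int] = None,
    n_accept: int = 5,
    rng: Optional[np.random.Generator] = None,
    draw_limit: int = DEFAULT_DRAW_LIMIT,
    dt: float = DEFAULT_DT,
    v_max: float = DEFAULT_V_MAX,
) -> Tuple[List[float], List[dict]]:
    """Draw ``n_accept`` distinct accepted PV fractions for one subject.

    Returns ``(accepted, draw_log)`` where the log records every draw with
    its treatment count and accept/reject decision.
    """
    if n_accept < 1:
        raise InvalidParameterError("n_accept must be at least 1")
    if rng is None:
        if seed is None:
            raise InvalidParameterError("a seed or rng is required")
        rng = np.random.default_rng(seed)
    if bounds is None:
        bounds = SafetyBounds.default_for(subject.B)
    lo, hi = ACCEPT_RANGE
    accepted: List[float] = []
    log: List[dict] = []
    for _ in range(draw_limit):
        lam = float(rng.uniform(0.0, 1.0))
        n = count_treatments_365(subject.params(lam), bounds, dt=dt, v_max=v_max)
        ok = (lo <= n <= hi) and lam not in accepted
        log.append({"lambda": lam, "n_treatments": n, "accepted": ok})
        if ok:
            accepted.append(lam)
            if len(accepted) == n_accept:
                return accepted, log
    raise ErythroplanError(
        f"subject {subject.id}: draw limit {draw_limit} reached with only "
        f"{len(accepted)} accepted values"
    )


def generate_insilico_cohort(
    subjects: Optional[Sequence[SubjectRecord]] = None,
    bounds: Optional[SafetyBounds] = None,
    seed: int = 0,
    n_accept: int = 5,
    dt: float = DEFAULT_DT,
    v_max: float = DEFAULT_V_MAX,
) -> List[PatientParams]:
    """Run rejection sampling across the cohort.

    With the packaged 28 subjects and the default 5 acceptances each, this
    yields 140 (subject, lambda_PV) configurations.  Per-subject safety
    bounds default to ``SafetyBounds.default_for(B)``.
    """
    if subjects is None:
        subjects = load_reference_cohort()
    rng = np.random.default_rng(seed)
    configs: List[PatientParams] = []
    for subject in subjects:
        b = bounds if bounds is not None else SafetyBounds.default_for(subject.B)
        lams, _ = sample_pv_fraction(
            subject, bounds=b, rng=rng, n_accept=n_accept, dt=dt, v_max=v_max
        )
        configs.extend(subject.params(lam) for lam in lams)
    return configs


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Serialize subject records to the packaged CSV layout."""
    return pd.DataFrame(
        [
            {
                "id": s.id, "gamma": s.gamma, "beta": s.beta,
                "B": s.B, "V_pat": s.v_pat,
                **{f"lambda_{k + 1}": l for k, l in enumerate(s.lambdas)},
            }
            for s in subjects
        ]
    )


# ---------------------------------------------------------------------------
# synthetic measurements
# ---------------------------------------------------------------------------

def synth_measurements(
    params: PatientParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    x0=None,
    schedule=None,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Noisy tHb observations of a simulated trajectory.

    Simulates the patient over the span of ``times`` (optionally under a
    binary schedule) and returns ``eta_i = x3(t_i) + N(0, noise_sd)``
    as a DataFrame with columns (t, thb, sigma).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise InvalidParameterError("times must be non-negative and strictly increasing")
    if schedule is not None:
        n = np.asarray(getattr(schedule, "U", schedule)).size - 1
        horizon = n * dt
        if horizon < times[-1] - 1e-9:
            raise InvalidParameterError("schedule grid does not cover the sampling times")
    else:
        horizon = float(np.ceil(times[-1] / dt)) * dt
    from .model import healthy_steady_state  # local import to avoid cycle noise

    if x0 is None:
        x0 = healthy_steady_state(params)
    traj = simulate(params, x0, horizon, dt=dt, schedule=schedule)
    x3 = np.interp(times, traj.times, traj.x3)
    rng = np.random.default_rng(seed)
    eta = x3 + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else x3.copy()
    # the generator knows its own noise level; downstream weighting uses it
    # (unit weights when the series is noiseless)
    sigma = np.full_like(times, noise_sd if noise_sd > 0 else 1.0)
    return pd.DataFrame({"t": times, "thb": eta, "sigma": sigma})
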
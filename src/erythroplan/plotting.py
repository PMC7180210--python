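"""Basic trajectory and schedule figures."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .calendars import SafetyBounds, Schedule
from .model import Trajectory


def plot_trajectory(
    trajectory: Trajectory,
    bounds: Optional[SafetyBounds] = None,
    schedule: Optional[Schedule] = None,
    ax=None,
):
    """Erythrocyte-mass trajectory with optional bounds and treatment marks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    ax.plot(trajectory.times, trajectory.x3, color="k", lw=1.2, label="tHb $x_3$")
    if bounds is not None:
        ax.axhline(bounds.x3_up, color="purple", ls="--", lw=1, label="$X_{3,up}$")
        ax.axhline(bounds.x3_lo, color="gray", ls=":", lw=1, label="$X_{3,lo}$")
    if schedule is not None:
        for i in schedule.treatment_indices:
            ax.axvline(trajectory.times[i], color="tab:red", alpha=0.4, lw=0.8)
    ax.set_xlabel("time [day]")
    ax.set_ylabel("erythrocyte mass [g]")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_control(times, u, ax=None):
    """Relaxed control over time (step plot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    ax.step(times[:-1], u, where="post", color="tab:blue")
    ax.set_xlabel("time [day]")
    ax.set_ylabel("u(t)")
    ax.set_ylim(-0.02, 1.02)
    return ax
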
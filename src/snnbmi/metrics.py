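"""Trajectory metrics and encoder-ON/OFF condition comparison.

Metrics per trajectory:

* closest-point distance — minimum Euclidean distance of any visited position
  to the target;
* within-trajectory variance (wtv) — with ``Cx`` and ``Cy`` the per-axis
  variances of the per-step displacements, ``wtv = sqrt(Cx^2 + Cy^2)``; low
  wtv means straight, repeatable motion;
* steps to convergence — index of the first position inside the target disc
  (non-converged trials count at the step cap);
* DT/OT — each decoded force is split into a signed component directed to the
  target (``DT = F . u`` with ``u`` the unit vector from the position to the
  target; negative means divergent) and the non-negative magnitude of the
  orthogonal remainder (``OT``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .loop import Trajectory, Workspace

__all__ = [
    "SessionSummary",
    "ComparisonReport",
    "closest_point_distance",
    "within_trajectory_variance",
    "steps_to_convergence",
    "dt_ot_components",
    "summarize_session",
    "compare_conditions",
]


def closest_point_distance(traj: Trajectory, target) -> float:
    """Minimum distance of any trajectory position to the target."""
    pos = np.asarray(traj.positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty trajectory")
    return float(np.min(np.linalg.norm(pos - np.asarray(target, dtype=float), axis=1)))


def within_trajectory_variance(traj: Trajectory) -> float:
    """``sqrt(Cx^2 + Cy^2)`` over the per-step displacement variances.

    ``Cx``/``Cy`` are the sample variances (ddof=1) of the x/y displacement
    components.  Requires at least two displacements.
    """
    disp = np.diff(np.asarray(traj.positions, dtype=float), axis=0)
    if disp.shape[0] < 2:
        raise ValueError("wtv needs at least 2 displacements")
    cx = float(np.var(disp[:, 0], ddof=1))
    cy = float(np.var(disp[:, 1], ddof=1))
    return float(np.hypot(cx, cy))


def steps_to_convergence(traj: Trajectory, workspace: Workspace) -> int | None:
    """Index of the first position inside the target disc; None if never."""
    d = np.linalg.norm(
        np.asarray(traj.positions, dtype=float) - workspace.target, axis=1
    )
    hits = np.flatnonzero(d <= workspace.target_radius_cm)
    return int(hits[0]) if hits.size else None


def dt_ot_components(force, pos, target) -> tuple[float, float]:
    """Signed directed-to-target component and orthogonal magnitude of a force."""
    force = np.asarray(force, dtype=float)
    v = np.asarray(target, dtype=float) - np.asarray(pos, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("position coincides with the target; direction undefined")
    u = v / n
    dt = float(force @ u)
    ot = float(np.linalg.norm(force - dt * u))
    return dt, ot


@dataclass
class SessionSummary:
    """Aggregate metrics of one session, with the raw per-trajectory values."""

    mode: str
    n_trajectories: int
    mean_closest_distance: float
    mean_wtv: float
    mean_steps: float
    mean_dt: float
    mean_ot: float
    convergence_rate: float
    per_start: dict = field(default_factory=dict)
    closest_distances: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    wtvs: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    steps: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self):
        if self.n_trajectories <= 0:
            raise ValueError("summary needs at least one trajectory")
        if not 0.0 <= self.convergence_rate <= 1.0:
            raise ValueError("convergence_rate must be in [0, 1]")


def summarize_session(
    trajectories: list[Trajectory], workspace: Workspace, step_cap: int = 100
) -> SessionSummary:
    """Aggregate all metrics over a session.

    DT/OT are averaged over every step of every trajectory (steps taken at
    the target itself, where the direction is undefined, are skipped).
    Non-converged trajectories contribute ``step_cap`` to the mean step
    count; trajectories too short for a wtv (fewer than two steps) are
    excluded from the wtv mean.
    """
    if not trajectories:
        raise ValueError("empty session")
    dists = np.array([closest_point_distance(t, workspace.target) for t in trajectories])
    wtvs = np.array(
        [within_trajectory_variance(t) for t in trajectories if t.steps_used >= 2]
    )
    steps = np.array(
        [
            s if (s := steps_to_convergence(t, workspace)) is not None else step_cap
            for t in trajectories
        ],
        dtype=float,
    )
    dts, ots = [], []
    for t in trajectories:
        for s in range(t.steps_used):
            pos = t.positions[s]
            if np.array_equal(pos, workspace.target):
                continue
            dt, ot = dt_ot_components(t.forces[s], pos, workspace.target)
            dts.append(dt)
            ots.append(ot)
    per_start: dict[int, dict] = {}
    for si in sorted({t.start_index for t in trajectories}):
        sel = [t for t in trajectories if t.start_index == si]
        per_start[si] = {
            "n": len(sel),
            "mean_closest_distance": float(
                np.mean([closest_point_distance(t, workspace.target) for t in sel])
            ),
            "convergence_rate": float(np.mean([t.converged for t in sel])),
        }
    return SessionSummary(
        mode=trajectories[0].mode,
        n_trajectories=len(trajectories),
        mean_closest_distance=float(dists.mean()),
        mean_wtv=float(wtvs.mean()) if wtvs.size else float("nan"),
        mean_steps=float(steps.mean()),
        mean_dt=float(np.mean(dts)) if dts else float("nan"),
        mean_ot=float(np.mean(ots)) if ots else float("nan"),
        convergence_rate=float(np.mean([t.converged for t in trajectories])),
        per_start=per_start,
        closest_distances=dists,
        wtvs=wtvs,
        steps=steps,
    )


@dataclass
class ComparisonReport:
    """Encoder-ON vs encoder-OFF comparison.

    Percent decreases are ``100 * (off - on) / off`` on the session means
    (positive when the ON condition is smaller).  The DT component is
    reported as both condition means and their difference rather than a
    percentage, because the OFF-condition DT can be negative.
    """

    pct_decrease_closest_distance: float
    pct_decrease_wtv: float
    pct_decrease_steps: float
    dt_on: float
    dt_off: float
    dt_difference: float
    ot_on: float
    ot_off: float
    t_statistic: float
    p_value: float
    on: SessionSummary = field(repr=False, default=None)
    off: SessionSummary = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "pct_decrease_closest_distance": self.pct_decrease_closest_distance,
            "pct_decrease_wtv": self.pct_decrease_wtv,
            "pct_decrease_steps": self.pct_decrease_steps,
            "dt_on": self.dt_on,
            "dt_off": self.dt_off,
            "dt_difference": self.dt_difference,
            "ot_on": self.ot_on,
            "ot_off": self.ot_off,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def _pct_decrease(off: float, on: float) -> float:
    if off == 0:
        return 0.0 if on == 0 else float("-inf")
    return 100.0 * (off - on) / off


def compare_conditions(on: SessionSummary, off: SessionSummary) -> ComparisonReport:
    """Percent changes of the session means plus a two-sample t-test.

    The t-test (pooled-variance independent samples) compares the per-
    trajectory closest-point distances between conditions.
    """
    t_stat, p = stats.ttest_ind(on.closest_distances, off.closest_distances)
    return ComparisonReport(
        pct_decrease_closest_distance=_pct_decrease(
            off.mean_closest_distance, on.mean_closest_distance
        ),
        pct_decrease_wtv=_pct_decrease(off.mean_wtv, on.mean_wtv),
        pct_decrease_steps=_pct_decrease(off.mean_steps, on.mean_steps),
        dt_on=on.mean_dt,
        dt_off=off.mean_dt,
        dt_difference=on.mean_dt - off.mean_dt,
        ot_on=on.mean_ot,
        ot_off=off.mean_ot,
        t_statistic=float(t_stat),
        p_value=float(p),
        on=on,
        off=off,
    )
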
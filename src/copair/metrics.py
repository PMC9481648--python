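"""Trajectory similarity metrics and configuration-optimality analysis.

Two time-normalized trajectories (same number N of samples) are compared
with the study's linear and angular distances

    d_xy(X1, X2)    = (1/N) sum_i sqrt((x1_i - x2_i)^2 + (y1_i - y2_i)^2)
    d_theta(X1, X2) = (1/N) sum_i |theta1_i - theta2_i|

computed on unwrapped heading signals.  The *travelled distance* of an
entity is the straight-line start-to-goal distance (not arc length).  A
chosen table configuration is *optimal* for Subject 1, Subject 2 or the
pair when it minimizes that subject's (or the summed) travelled distance
over the two possible pi-rotated table placements at the goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._angles import unwrap, wrap_angle
from .trajectory import PlanarPose, Trajectory

CONFIGS = ("A", "B")
DEFAULT_GRIP_OFFSET = 0.9  # m, subject CoM offset from table centre along the table axis

__all__ = [
    "DistanceReport",
    "GoalSpec",
    "OptimalityLabel",
    "travelled_distance",
    "curve_distance",
    "average_trajectory",
    "reverse_trajectory",
    "symmetry_distances",
    "classify_configuration_optimality",
    "subject_positions",
]


@dataclass(frozen=True)
class DistanceReport:
    """Linear (m) and angular (rad) mean pointwise distances."""

    d_xy: float
    d_theta: float

    def __iter__(self):
        yield self.d_xy
        yield self.d_theta


@dataclass(frozen=True)
class GoalSpec:
    """Geometry of one goal position of the carriage protocol.

    The table starts at ``start_table_pose``; at the goal its centre sits
    at the pose of configuration A, or the same pose rotated by pi
    (configuration B).  Subjects hold opposite sides: their planar CoM
    anchors sit at ``+-grip_offset`` metres from the table centre along
    the table's long axis (Subject 1 on the negative side at the start).
    """

    goal_id: int
    center: tuple
    theta_f: float
    start_table_pose: PlanarPose = PlanarPose(0.0, 0.0, 0.0)
    grip_offset: float = DEFAULT_GRIP_OFFSET

    def __post_init__(self) -> None:
        if not 1 <= self.goal_id <= 9:
            raise ValueError("goal_id must be in 1..9")
        if self.grip_offset <= 0:
            raise ValueError("grip_offset must be positive")

    @property
    def table_pose_per_config(self) -> dict:
        cx, cy = self.center
        return {
            "A": PlanarPose(cx, cy, self.theta_f),
            "B": PlanarPose(cx, cy, self.theta_f + np.pi),
        }

    @property
    def global_distance(self) -> float:
        """Straight-line start-to-goal distance of the table centre (m)."""
        dx = self.center[0] - self.start_table_pose.x
        dy = self.center[1] - self.start_table_pose.y
        return float(np.hypot(dx, dy))

    @property
    def orientation_change(self) -> bool:
        """Whether the table axis direction differs between start and goal (mod pi)."""
        d = wrap_angle(self.theta_f - self.start_table_pose.theta)
        return not (abs(d) < 1e-9 or abs(abs(d) - np.pi) < 1e-9)


@dataclass(frozen=True)
class OptimalityLabel:
    optimal_for_subject1: bool
    optimal_for_subject2: bool
    optimal_for_pair: bool


def subject_positions(table_pose: PlanarPose, grip_offset: float = DEFAULT_GRIP_OFFSET):
    """Planar CoM anchor of each subject for a given table pose.

    Subject 1 sits at -grip_offset along the table axis, Subject 2 at
    +grip_offset.  Under the pi-rotated configuration the axis flips, so
    the subjects end up on swapped sides of the goal marks.
    """
    u = np.array([np.cos(table_pose.theta), np.sin(table_pose.theta)])
    c = table_pose.position()
    return c - grip_offset * u, c + grip_offset * u


def travelled_distance(traj: Trajectory) -> float:
    """Straight-line distance between the first and last samples (m)."""
    return float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))


def _check_comparable(x1: Trajectory, x2: Trajectory) -> None:
    if x1.n != x2.n:
        raise ValueError(f"trajectories must share N (got {x1.n} and {x2.n})")


def curve_distance(x1: Trajectory, x2: Trajectory) -> DistanceReport:
    """Mean pointwise linear and angular distances between two trajectories."""
    _check_comparable(x1, x2)
    d_xy = float(np.mean(np.hypot(x1.x - x2.x, x1.y - x2.y)))
    d_theta = float(np.mean(np.abs(x1.theta - x2.theta)))
    return DistanceReport(d_xy, d_theta)


def average_trajectory(trajs: Sequence[Trajectory]) -> Trajectory:
    """Per-sample arithmetic mean of a set of same-length trajectories.

    Heading is averaged arithmetically on the unwrapped signals (the
    trajectories are continuous; a circular mean is deliberately not
    used).  Averaging across the two table configurations is refused by
    callers upstream — it would mix pi-rotated geometries.
    """
    if len(trajs) == 0:
        raise ValueError("cannot average an empty list of trajectories")
    n = trajs[0].n
    entity = trajs[0].entity
    for tr in trajs:
        _check_comparable(trajs[0], tr)
        if tr.entity != entity:
            raise ValueError("cannot average trajectories of different entities")
    x = np.mean([tr.x for tr in trajs], axis=0)
    y = np.mean([tr.y for tr in trajs], axis=0)
    theta = np.mean([tr.theta for tr in trajs], axis=0)
    return Trajectory(entity, trajs[0].t.copy(), x, y, theta, trajs[0].normalized)


def reverse_trajectory(traj: Trajectory) -> Trajectory:
    """Reverse the sample order (the time axis is kept); theta re-unwrapped."""
    return Trajectory(
        traj.entity,
        traj.t.copy(),
        traj.x[::-1].copy(),
        traj.y[::-1].copy(),
        unwrap(traj.theta[::-1]),
        traj.normalized,
    )


def symmetry_distances(forward: Trajectory, return_: Trajectory) -> DistanceReport:
    """How far a return path is from the time-reversed forward path.

    Small values mean the pair retraced its forward path backwards; the
    smaller the distances, the more symmetrical the two paths.
    """
    rev = reverse_trajectory(return_)
    # re-anchor the reversed heading branch to the forward one (unwrapping a
    # reversed signal can land 2*pi away without changing the geometry)
    k = np.round((forward.theta[0] - rev.theta[0]) / (2.0 * np.pi))
    if k != 0:
        rev = Trajectory(rev.entity, rev.t, rev.x, rev.y, rev.theta + 2.0 * np.pi * k,
                         rev.normalized)
    return curve_distance(forward, rev)


def per_subject_distances(goal: GoalSpec) -> dict:
    """Straight-line travelled distance of each subject under each configuration."""
    s1_start, s2_start = subject_positions(goal.start_table_pose, goal.grip_offset)
    out = {}
    for cfg, pose in goal.table_pose_per_config.items():
        s1_end, s2_end = subject_positions(pose, goal.grip_offset)
        out[cfg] = (
            float(np.linalg.norm(s1_end - s1_start)),
            float(np.linalg.norm(s2_end - s2_start)),
        )
    return out


def classify_configuration_optimality(
    goal: GoalSpec, chosen_config: str, tol: float = 1e-9
) -> OptimalityLabel:
    """Label a chosen table configuration as optimal per subject and for the pair.

    The chosen configuration is optimal for Subject i (for the pair) when
    its travelled distance D_i (sum D_1 + D_2) is no larger than under the
    alternative configuration; exact ties mark both configurations
    optimal.
    """
    if chosen_config not in CONFIGS:
        raise ValueError("chosen_config must be 'A' or 'B'")
    dists = per_subject_distances(goal)
    other = "B" if chosen_config == "A" else "A"
    return label_from_distances(dists[chosen_config], dists[other], tol)


def label_from_distances(d_chosen, d_other, tol: float = 1e-9) -> OptimalityLabel:
    """Optimality flags from (D1, D2) under the chosen and alternative configuration."""
    d1c, d2c = d_chosen
    d1o, d2o = d_other
    return OptimalityLabel(
        optimal_for_subject1=d1c <= d1o + tol,
        optimal_for_subject2=d2c <= d2o + tol,
        optimal_for_pair=(d1c + d2c) <= (d1o + d2o) + tol,
    )
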
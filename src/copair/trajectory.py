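"""Core planar-trajectory containers.

The study tracks three entities per carriage trial — Subject 1, Subject 2
and the table — each reduced to a planar pose (x, y, theta): horizontal
centre-of-mass position plus pelvis (or table long-axis) heading in the
global frame.  A :class:`Trajectory` is a time-indexed pose sequence,
either on the raw acquisition clock (seconds) or time-normalized to
0–100 % on a fixed number of samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._angles import unwrap

ENTITIES = ("subject1", "subject2", "table")

__all__ = ["PlanarPose", "Trajectory", "TrialRecord", "ENTITIES"]


@dataclass(frozen=True)
class PlanarPose:
    """A planar pose: position in metres, heading in radians."""

    x: float
    y: float
    theta: float

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta], dtype=float)


@dataclass
class Trajectory:
    """Time-indexed planar pose sequence for one entity.

    Parameters
    ----------
    entity : str
        One of ``"subject1"``, ``"subject2"``, ``"table"``.
    t : ndarray
        Time stamps: seconds for raw data, 0–100 (%) when ``normalized``.
    x, y : ndarray
        Horizontal CoM position (m).
    theta : ndarray
        Heading (rad), stored unwrapped (no ±2π jumps between samples).
    normalized : bool
        Whether ``t`` is normalized time on [0, 100].
    """

    entity: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValueError(f"unknown entity {self.entity!r}; expected one of {ENTITIES}")
        for name in ("t", "x", "y", "theta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if any(getattr(self, name).size != n for name in ("x", "y", "theta")):
            raise ValueError("t, x, y, theta must have identical lengths")
        if not np.all(np.isfinite(np.concatenate([self.t, self.x, self.y, self.theta]))):
            raise ValueError("trajectory contains non-finite samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.any(np.abs(np.diff(self.theta)) >= np.pi):
            raise ValueError("theta must be unwrapped (consecutive jumps < pi)")

    @property
    def n(self) -> int:
        return int(self.t.size)

    @classmethod
    def from_poses(
        cls,
        entity: str,
        t: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        theta: np.ndarray,
        normalized: bool = False,
    ) -> "Trajectory":
        """Build a trajectory, unwrapping ``theta`` first."""
        return cls(entity, np.asarray(t, float), np.asarray(x, float),
                   np.asarray(y, float), unwrap(theta), normalized)

    def pose(self, i: int) -> PlanarPose:
        return PlanarPose(float(self.x[i]), float(self.y[i]), float(self.theta[i]))

    def xy(self) -> np.ndarray:
        """(n, 2) array of positions."""
        return np.column_stack([self.x, self.y])

    def copy(self) -> "Trajectory":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), theta=self.theta.copy()
        )

    # -- JSON round trip (schema: {entity, n, t_norm[], x[], y[], theta[]}) --

    def to_dict(self) -> dict:
        key = "t_norm" if self.normalized else "t"
        return {
            "entity": self.entity,
            "n": self.n,
            key: self.t.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "theta": self.theta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        normalized = "t_norm" in d
        t = d["t_norm"] if normalized else d["t"]
        return cls(d["entity"], np.asarray(t, float), np.asarray(d["x"], float),
                   np.asarray(d["y"], float), np.asarray(d["theta"], float), normalized)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "Trajectory":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TrialRecord:
    """One carriage trial: metadata plus the three entity trajectories.

    ``scenario`` follows the study design: 1 and 2 are the single-leader
    conditions, 3 is the shared-knowledge condition.  All return paths are
    performed under scenario-3 conditions; ``block`` records in which of
    the three experimental blocks the trial took place (return repeats).
    """

    pair_id: int
    goal_id: int
    scenario: int
    direction: str  # "forward" | "return"
    config: str  # "A" | "B" — table configuration at the goal (returns: the one departed from)
    block: int
    travel_time: float
    subject1: Trajectory
    subject2: Trajectory
    table: Trajectory
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "return"):
            raise ValueError("direction must be 'forward' or 'return'")
        if self.config not in ("A", "B"):
            raise ValueError("config must be 'A' or 'B'")
        if self.travel_time <= 0:
            raise ValueError("travel_time must be positive")

    def trajectories(self) -> Iterable[Trajectory]:
        return (self.subject1, self.subject2, self.table)

    def trajectory(self, entity: str) -> Trajectory:
        return {"subject1": self.subject1, "subject2": self.subject2, "table": self.table}[entity]
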
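"""Synthetic carriage-trial generator emulating the study design.

The experimental layout being emulated: 20 pairs carry a 1.22 x 0.8 m
table from a fixed start to nine goal positions 2.7–5.4 m away, under
three scenarios (1: only Subject 1 knows the goal, 2: only Subject 2,
3: both).  Scenario blocks run one after the other; every return to the
start is performed with both subjects informed, i.e. under scenario-3
conditions, so the three blocks yield three same-condition returns per
goal.  Each pair therefore contributes 54 trajectories (9 goals x 2 paths
x 3 blocks); 20 pairs give 1080 trials and 3240 entity trajectories.

Trials are built from the coupled optimal-control model: the base
trajectory is the model solution for the goal, and inter-pair variability
is added as smooth endpoint-pinned perturbation fields (sums of 3–6
low-frequency sinusoids per coordinate) scaled so the expected linear and
angular distance to the base matches the design's noise levels (default
0.20 m / 0.20 rad, the regime measured on the cohort).  The table path is
the midpoint of the two carriers with a smaller perturbation of its own,
so table variability stays below subject variability.  Scenario effects
enter only through travel times (drawn per scenario) and the
configuration-choice policy; path geometry is scenario-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._angles import unwrap
from .ioc import FitDataset, FitEntry
from .metrics import (
    GoalSpec,
    average_trajectory,
    per_subject_distances,
    subject_positions,
)
from .oc import CostWeights, CoupledOCModel, OCProblem, OCSolution, NOMINAL_SPEED
from .trajectory import Trajectory, TrialRecord

__all__ = [
    "StudyDesign",
    "make_goal_layout",
    "preferred_config",
    "default_config_policy",
    "generate_pair_trial",
    "generate_dataset",
    "sample_travel_times",
    "build_fit_dataset",
    "carriage_problem",
]

# (goal_id, distance m, azimuth deg, final table heading rad)
_GOAL_TABLE = (
    (1, 4.5, 0.0, 0.0),
    (2, 4.7, 0.0, np.pi / 2),  # on-axis quarter turn: equal distances either config
    (3, 2.7, -35.0, 0.0),
    (4, 3.2, 30.0, np.pi / 2),
    (5, 3.8, -20.0, 0.0),
    (6, 4.2, 40.0, np.pi / 2),
    (7, 4.9, -30.0, 0.0),
    (8, 5.4, 20.0, np.pi / 2),
    (9, 4.5, 90.0, 0.0),
)
_JITTERED_GOALS = (3, 4, 5, 6, 7, 8)  # goals whose azimuth may be jittered


def make_goal_layout(seed: int = 0, azimuth_jitter_deg: float = 4.0) -> list:
    """The nine-goal layout of the protocol.

    Distances span 2.7–5.4 m from the start; goals 2, 4, 6 and 8 require a
    quarter turn of the table (orientation change); goal 2 sits on the
    table's start axis, so both subjects walk the same distance whichever
    configuration is chosen.  ``seed`` jitters the azimuth of the oblique
    goals slightly; distances and the special goals are fixed.
    """
    rng = np.random.default_rng(seed)
    goals = []
    for gid, r, az_deg, theta_f in _GOAL_TABLE:
        az = np.deg2rad(az_deg)
        if gid in _JITTERED_GOALS:
            az += np.deg2rad(rng.uniform(-azimuth_jitter_deg, azimuth_jitter_deg))
        goals.append(GoalSpec(gid, (r * np.cos(az), r * np.sin(az)), theta_f))
    return goals


def preferred_config(goal: GoalSpec) -> str:
    """The pair-optimal configuration of a goal ('A' on ties)."""
    dists = per_subject_distances(goal)
    return "A" if sum(dists["A"]) <= sum(dists["B"]) else "B"


def default_config_policy(goals: Sequence[GoalSpec]) -> dict:
    """Probability of choosing the pair-optimal configuration, per (scenario, goal).

    Blocks 1 and 2 are exploratory (p = 0.7 everywhere); by block 3 the
    choice is settled for same-orientation goals (p = 1) while the
    quarter-turn goals stay ambiguous (p = 0.5) — their two configurations
    swap which subject walks further, and for the on-axis goal they are
    exactly equivalent.
    """
    policy = {}
    for goal in goals:
        for scenario in (1, 2):
            policy[(scenario, goal.goal_id)] = 0.7
        policy[(3, goal.goal_id)] = 0.5 if goal.orientation_change else 1.0
    return policy


@dataclass
class StudyDesign:
    """Design constants of the emulated study (defaults = the study's values)."""

    n_pairs: int = 20
    goals: list = field(default_factory=make_goal_layout)
    scenarios: tuple = (1, 2, 3)
    base_travel_time: dict = field(default_factory=lambda: {1: 9.6, 2: 8.9, 3: 8.4})
    travel_time_sd: dict = field(default_factory=lambda: {1: 2.2, 2: 1.8, 3: 1.5})
    min_travel_time: float = 3.0
    noise_xy: float = 0.20  # m, expected linear distance of a trial to its base path
    noise_theta: float = 0.20  # rad, expected angular distance to the base path
    table_noise_xy: float = 0.05  # m, extra table-path perturbation
    table_noise_theta: float = 0.05  # rad
    config_policy: Optional[dict] = None
    seed: int = 0
    n_norm: int = 500
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        for nm in ("noise_xy", "noise_theta", "table_noise_xy", "table_noise_theta"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")
        for goal in self.goals:
            if not 2.7 - 1e-9 <= goal.global_distance <= 5.4 + 1e-9:
                raise ValueError(
                    f"goal {goal.goal_id} distance {goal.global_distance:.2f} m outside "
                    "the protocol range [2.7, 5.4] m"
                )
        if self.config_policy is None:
            self.config_policy = default_config_policy(self.goals)

    def goal(self, goal_id: int) -> GoalSpec:
        for g in self.goals:
            if g.goal_id == goal_id:
                return g
        raise KeyError(f"no goal with id {goal_id}")


def _facing_headings(p1: np.ndarray, p2: np.ndarray):
    th1 = float(np.arctan2(p2[1] - p1[1], p2[0] - p1[0]))
    return th1, th1 + np.pi


def carriage_problem(goal: GoalSpec, config: str, direction: str,
                     dt: float = 0.05, T: Optional[float] = None) -> OCProblem:
    """The coupled OC problem for one goal/configuration/direction.

    Forward: from the start table pose to the goal pose under ``config``.
    Return: back from that placement to the start pose in its original
    orientation.  Subjects hold opposite grip points and face each other
    at both ends; start velocities are zero.
    """
    start_pose = goal.start_table_pose
    goal_pose = goal.table_pose_per_config[config]
    if direction == "forward":
        from_pose, to_pose = start_pose, goal_pose
    elif direction == "return":
        from_pose, to_pose = goal_pose, start_pose
    else:
        raise ValueError("direction must be 'forward' or 'return'")
    s1s, s2s = subject_positions(from_pose, goal.grip_offset)
    s1f, s2f = subject_positions(to_pose, goal.grip_offset)
    th1s, th2s = _facing_headings(s1s, s2s)
    th1f, th2f = _facing_headings(s1f, s2f)
    x_start = np.array([*s1s, th1s, *s2s, th2s])
    x_goal = np.array([*s1f, th1f, *s2f, th2f])
    if T is None:
        d = 0.5 * (np.linalg.norm(s1f - s1s) + np.linalg.norm(s2f - s2s))
        T = max(2.0, round(max(d, 0.6) / NOMINAL_SPEED / dt) * dt)
    return OCProblem(x_start, x_goal, T=T, dt=dt)


def _base_solution(goal: GoalSpec, config: str, direction: str, weights: CostWeights,
                   design: StudyDesign, cache: Optional[dict]) -> OCSolution:
    key = (goal.goal_id, config, direction)
    if cache is not None and key in cache:
        return cache[key]
    problem = carriage_problem(goal, config, direction, dt=design.dt)
    model = CoupledOCModel(weights=weights, dt=design.dt, n_norm=design.n_norm)
    sol = model.solve(problem)
    if cache is not None:
        cache[key] = sol
    return sol


def _smooth_field(rng: np.random.Generator, n: int) -> np.ndarray:
    """A smooth random field on n samples, zero at both endpoints."""
    s = np.linspace(0.0, 1.0, n)
    k_max = rng.integers(3, 7)
    out = np.zeros(n)
    for k in range(1, k_max + 1):
        out += rng.normal(0.0, 1.0 / k) * np.sin(k * np.pi * s)
    return out


def _magnitude_factor(rng: np.random.Generator) -> float:
    """Per-trial noise magnitude multiplier: mean 1, sd 0.5 (gamma)."""
    return float(rng.gamma(4.0, 0.25))


def _perturb_positions(rng, n, target_xy):
    dx, dy = _smooth_field(rng, n), _smooth_field(rng, n)
    mag = float(np.mean(np.hypot(dx, dy)))
    if mag < 1e-12 or target_xy == 0.0:
        return np.zeros(n), np.zeros(n)
    scale = target_xy * _magnitude_factor(rng) / mag
    return dx * scale, dy * scale


def _perturb_angle(rng, n, target_theta):
    dth = _smooth_field(rng, n)
    mag = float(np.mean(np.abs(dth)))
    if mag < 1e-12 or target_theta == 0.0:
        return np.zeros(n)
    return dth * (target_theta * _magnitude_factor(rng) / mag)


def _draw_travel_time(rng: np.random.Generator, mean: float, sd: float,
                      minimum: float) -> float:
    for _ in range(100):
        t = rng.normal(mean, sd)
        if t >= minimum:
            return float(t)
    return float(minimum)


def _trial_rng(design: StudyDesign, pair_id: int, goal_id: int, scenario: int,
               direction: str, block: int, purpose: int) -> np.random.Generator:
    """Deterministic per-trial generator: master seed hashed with the trial coordinates."""
    dcode = 0 if direction == "forward" else 1
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=design.seed,
            spawn_key=(pair_id, goal_id, scenario, dcode, block, purpose),
        )
    )


def generate_pair_trial(
    goal: GoalSpec,
    scenario: int,
    direction: str,
    weights: CostWeights,
    design: StudyDesign,
    pair_id: int,
    block: int,
    config: str,
    cache: Optional[dict] = None,
) -> TrialRecord:
    """Generate one trial: model base path plus smooth endpoint-pinned noise."""
    sol = _base_solution(goal, config, direction, weights, design, cache)
    n = design.n_norm
    rng = _trial_rng(design, pair_id, goal.goal_id, scenario, direction, block, 1)

    subj = {}
    for ent, base in (("subject1", sol.subject1), ("subject2", sol.subject2)):
        dx, dy = _perturb_positions(rng, n, design.noise_xy)
        dth = _perturb_angle(rng, n, design.noise_theta)
        subj[ent] = Trajectory(ent, base.t.copy(), base.x + dx, base.y + dy,
                               base.theta + dth, normalized=True)

    # table: midpoint of the carriers plus its own smaller perturbation;
    # heading follows the inter-subject axis (the table's long axis)
    tx = 0.5 * (subj["subject1"].x + subj["subject2"].x)
    ty = 0.5 * (subj["subject1"].y + subj["subject2"].y)
    tth = unwrap(np.arctan2(subj["subject2"].y - subj["subject1"].y,
                            subj["subject2"].x - subj["subject1"].x))
    dx, dy = _perturb_positions(rng, n, design.table_noise_xy)
    dth = _perturb_angle(rng, n, design.table_noise_theta)
    table = Trajectory("table", subj["subject1"].t.copy(), tx + dx, ty + dy,
                       tth + dth, normalized=True)

    tt_rng = _trial_rng(design, pair_id, goal.goal_id, scenario, direction, block, 2)
    travel_time = _draw_travel_time(
        tt_rng, design.base_travel_time[scenario], design.travel_time_sd[scenario],
        design.min_travel_time,
    )
    return TrialRecord(
        pair_id=pair_id,
        goal_id=goal.goal_id,
        scenario=scenario,
        direction=direction,
        config=config,
        block=block,
        travel_time=travel_time,
        subject1=subj["subject1"],
        subject2=subj["subject2"],
        table=table,
        meta={
            "global_distance": goal.global_distance,
            "orientation_change": goal.orientation_change,
            "preferred_config": preferred_config(goal),
            "horizon": sol.diagnostics["T"],
        },
    )


def _draw_config(design: StudyDesign, goal: GoalSpec, pair_id: int, block: int) -> str:
    p = design.config_policy[(block, goal.goal_id)]
    rng = _trial_rng(design, pair_id, goal.goal_id, block, "forward", block, 3)
    pref = preferred_config(goal)
    other = "B" if pref == "A" else "A"
    return pref if rng.random() < p else other


def generate_dataset(design: StudyDesign, weights: Optional[CostWeights] = None,
                     cache: Optional[dict] = None) -> list:
    """Generate the full factorial dataset: pairs x blocks x goals x 2 paths.

    Forward trials carry the scenario of their block; every return is
    performed under scenario-3 conditions (both subjects know the start
    position) and departs from the configuration its forward path chose.
    """
    if weights is None:
        weights = CostWeights.reference()
    if cache is None:
        cache = {}
    trials = []
    for pair_id in range(design.n_pairs):
        for block in design.scenarios:
            for goal in design.goals:
                config = _draw_config(design, goal, pair_id, block)
                trials.append(
                    generate_pair_trial(goal, block, "forward", weights, design,
                                        pair_id, block, config, cache)
                )
                trials.append(
                    generate_pair_trial(goal, 3, "return", weights, design,
                                        pair_id, block, config, cache)
                )
    return trials


def sample_travel_times(design: StudyDesign, seed: Optional[int] = None) -> pd.DataFrame:
    """Per-trial travel times of the design, without trajectory synthesis.

    Useful for calibrating the travel-time statistics in isolation; the
    draws match :func:`generate_dataset` when ``seed`` is None.
    """
    d = design
    if seed is not None:
        from dataclasses import replace as _replace

        d = _replace(design, seed=seed, goals=list(design.goals),
                     config_policy=dict(design.config_policy or {}))
    rows = []
    for pair_id in range(d.n_pairs):
        for block in d.scenarios:
            for goal in d.goals:
                for direction, scenario in (("forward", block), ("return", 3)):
                    rng = _trial_rng(d, pair_id, goal.goal_id, scenario, direction, block, 2)
                    tt = _draw_travel_time(
                        rng, d.base_travel_time[scenario], d.travel_time_sd[scenario],
                        d.min_travel_time,
                    )
                    rows.append(
                        {"pair_id": pair_id, "goal_id": goal.goal_id, "scenario": scenario,
                         "direction": direction, "block": block, "travel_time": tt}
                    )
    return pd.DataFrame(rows)


def build_fit_dataset(trials: list, design: StudyDesign, scenario: int = 3,
                      min_trials: int = 1) -> FitDataset:
    """Average the scenario-3 cells of a dataset into an IOC fit dataset.

    Forward entries are the scenario-3 forward cells (goal x observed
    configuration); return entries pool all returns (every return is a
    scenario-3 path) per goal x configuration.  With the default design
    this yields 13 forward + 18 return = 31 entries.
    """
    cells: dict = {}
    for tr in trials:
        if tr.direction == "forward" and tr.scenario != scenario:
            continue
        cells.setdefault((tr.direction, tr.goal_id, tr.config), []).append(tr)
    entries = []
    for direction in ("forward", "return"):
        for (dr, gid, config), cell in sorted(
            cells.items(), key=lambda kv: (kv[0][1], kv[0][2])
        ):
            if dr != direction or len(cell) < min_trials:
                continue
            goal = design.goal(gid)
            problem = carriage_problem(goal, config, direction, dt=design.dt)
            entries.append(
                FitEntry(
                    goal_id=gid,
                    config=config,
                    direction=direction,
                    problem=problem,
                    subject1=average_trajectory([t.subject1 for t in cell]),
                    subject2=average_trajectory([t.subject2 for t in cell]),
                )
            )
    return FitDataset(entries)
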
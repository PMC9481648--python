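"""Bi-level inverse optimal control: recover cost weights from trajectories.

The outer problem searches the 15 nonnegative cost weights (11 running,
4 terminal); the inner problem solves, for each dataset entry, the
coupled trajectory-generation problem at the candidate weights.  Entries
are scored against the measured (average) trajectories with the study's
curve distances, and the outer objective is

    (1/N_traj) sum_n  d_xy1 + d_xy2 + 1/2 (d_theta1 + d_theta2)

— the angular terms are halved to bring the linear and angular distances
to the same magnitude.  The outer search is a derivative-free Powell
method over log-weights (which enforces nonnegativity), with seeded
restarts.  For return paths the subjects' roles are exchanged before
fitting: walking back, the subject who faces the destination is the one
who faced the start on the way out.

Weights are only identifiable up to a global scale (scaling all weights
leaves the inner minimizer unchanged), so recovered weight vectors should
be compared after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .metrics import curve_distance
from .oc import CostWeights, CoupledOCModel, OCProblem, SolverError
from .trajectory import Trajectory

PENALTY = 10.0  # m-equivalents charged for an entry whose inner solve fails

__all__ = [
    "FitEntry",
    "FitDataset",
    "FitResult",
    "IOCWeightFitter",
    "ioc_objective",
    "role_switch_return",
    "fit_weights",
]


@dataclass
class FitEntry:
    """One average-trajectory pair to fit, with its generation problem."""

    goal_id: int
    config: str
    direction: str
    problem: OCProblem
    subject1: Trajectory
    subject2: Trajectory

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "return"):
            raise ValueError("direction must be 'forward' or 'return'")
        if self.subject1.n != self.subject2.n:
            raise ValueError("both subject trajectories must share N")


@dataclass
class FitDataset:
    """A nonempty set of fit entries, all time-normalized to the same N."""

    entries: list

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("fit dataset must be nonempty")
        n = self.entries[0].subject1.n
        if any(e.subject1.n != n for e in self.entries):
            raise ValueError("all entries must share the same N")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def role_switched(self) -> "FitDataset":
        """Apply the return-path role exchange to every return entry."""
        return FitDataset([role_switch_return(e) for e in self.entries])


def _swap_pose_slots(x: np.ndarray) -> np.ndarray:
    out = np.empty(6)
    out[:3], out[3:] = x[3:], x[:3]
    return out


def role_switch_return(entry: FitEntry) -> FitEntry:
    """Exchange the subject slots of a return entry (forward entries pass through).

    Applying the switch twice restores the original entry.
    """
    if entry.direction != "return":
        return entry
    prob = entry.problem
    swapped = replace(
        prob,
        x_start=_swap_pose_slots(prob.x_start),
        x_goal=_swap_pose_slots(prob.x_goal),
    )
    s1 = replace(entry.subject2, entity="subject1")
    s2 = replace(entry.subject1, entity="subject2")
    return FitEntry(entry.goal_id, entry.config, entry.direction, swapped, s1, s2)


def _score_entry(sol, entry: FitEntry):
    r1 = curve_distance(entry.subject1, sol.subject1)
    r2 = curve_distance(entry.subject2, sol.subject2)
    score = r1.d_xy + r2.d_xy + 0.5 * (r1.d_theta + r2.d_theta)
    return score, r1, r2


def ioc_objective(
    weights: CostWeights,
    dataset: FitDataset,
    dt: float = 0.05,
    max_iter: int = 120,
    tol: float = 1e-6,
    penalty: float = PENALTY,
    warm_cache: Optional[dict] = None,
):
    """Outer IOC objective at one weight set.

    Returns ``(objective, per_entry)`` where ``per_entry`` holds, for each
    entry, the two per-subject :class:`DistanceReport` objects, the entry
    score and a failure flag.  Failed inner solves contribute a fixed
    penalty so the outer search always sees a total function.
    """
    n = dataset.entries[0].subject1.n
    model = CoupledOCModel(weights=weights, dt=dt, max_iter=max_iter, tol=tol, n_norm=n)
    scores = []
    per_entry = []
    for idx, entry in enumerate(dataset.entries):
        warm = warm_cache.get(idx) if warm_cache is not None else None
        try:
            sol = model.solve(entry.problem, warm_controls=warm)
        except SolverError:
            scores.append(penalty)
            per_entry.append({"score": penalty, "failed": True,
                              "subject1": None, "subject2": None})
            continue
        if warm_cache is not None:
            warm_cache[idx] = sol.controls
        score, r1, r2 = _score_entry(sol, entry)
        scores.append(score)
        per_entry.append({"score": score, "failed": False, "subject1": r1, "subject2": r2})
    return float(np.mean(scores)), per_entry


@dataclass
class FitResult:
    """Outcome of one weight fit."""

    weights: CostWeights
    objective: float
    trace: np.ndarray  # best-so-far objective per outer evaluation
    per_entry: list
    n_evals: int
    budget_exhausted: bool

    @property
    def mean_d_xy(self) -> float:
        vals = [
            0.5 * (e["subject1"].d_xy + e["subject2"].d_xy)
            for e in self.per_entry
            if not e["failed"]
        ]
        return float(np.mean(vals)) if vals else float("nan")


class IOCWeightFitter(BaseEstimator):
    """Powell-based bi-level IOC fitter (scikit-learn style).

    ``fit(dataset)`` searches log-weights with seeded Powell restarts and
    exposes ``weights_``, ``objective_``, ``trace_`` and ``result_``.  The
    return-path role exchange is applied to the dataset once, up front.
    """

    def __init__(
        self,
        init_weights: Optional[CostWeights] = None,
        n_restarts: int = 3,
        max_evals: int = 200,
        seed: int = 0,
        dt: float = 0.05,
        inner_max_iter: int = 120,
        inner_tol: float = 1e-6,
        penalty: float = PENALTY,
        xtol: float = 1e-3,
        ftol: float = 1e-4,
        init_step: float = 0.3,
        apply_role_switch: bool = True,
    ):
        self.init_weights = init_weights
        self.n_restarts = n_restarts
        self.max_evals = max_evals
        self.seed = seed
        self.dt = dt
        self.inner_max_iter = inner_max_iter
        self.inner_tol = inner_tol
        self.penalty = penalty
        self.xtol = xtol
        self.ftol = ftol
        self.init_step = init_step
        self.apply_role_switch = apply_role_switch

    def fit(self, dataset: FitDataset, y=None) -> "IOCWeightFitter":
        if self.apply_role_switch:
            dataset = dataset.role_switched()
        init = self.init_weights if self.init_weights is not None else CostWeights.reference()
        rng = np.random.default_rng(self.seed)
        warm_cache: dict = {}
        trace: list = []
        best = {"z": np.log(np.maximum(init.as_vector(), 1e-12)), "f": np.inf}
        n_evals = 0
        budget_exhausted = False

        def objective_z(z):
            nonlocal n_evals
            n_evals += 1
            w = CostWeights.from_vector(np.exp(z))
            f, _ = ioc_objective(w, dataset, dt=self.dt, max_iter=self.inner_max_iter,
                                 tol=self.inner_tol, penalty=self.penalty,
                                 warm_cache=warm_cache)
            if f < best["f"]:
                best["f"], best["z"] = f, z.copy()
            trace.append(best["f"])
            return f

        z0 = best["z"].copy()
        for restart in range(max(1, self.n_restarts)):
            if restart == 0:
                z_init = z0
            else:  # seeded multiplicative perturbation of the incumbent
                z_init = best["z"] + rng.normal(0.0, 0.2, size=z0.size)
            res = minimize(
                objective_z,
                z_init,
                method="Powell",
                options={
                    "maxfev": self.max_evals,
                    "xtol": self.xtol,
                    "ftol": self.ftol,
                    "disp": False,
                    # initial coordinate steps of 0.3 in log-weight space
                    # (~x1.35): large enough to explore, small enough not to
                    # drift along weakly identified weight combinations
                    "direc": self.init_step * np.eye(z0.size),
                },
            )
            budget_exhausted = budget_exhausted or not res.success
        weights = CostWeights.from_vector(np.exp(best["z"]))
        final_obj, per_entry = ioc_objective(
            weights, dataset, dt=self.dt, max_iter=self.inner_max_iter,
            tol=self.inner_tol, penalty=self.penalty, warm_cache=warm_cache,
        )
        self.result_ = FitResult(
            weights=weights,
            objective=final_obj,
            trace=np.asarray(trace, dtype=float),
            per_entry=per_entry,
            n_evals=n_evals,
            budget_exhausted=budget_exhausted,
        )
        self.weights_ = weights
        self.objective_ = final_obj
        self.trace_ = self.result_.trace
        return self


def fit_weights(
    dataset: FitDataset,
    init: Optional[CostWeights] = None,
    **options,
) -> FitResult:
    """Fit cost weights to a dataset (thin wrapper over IOCWeightFitter)."""
    fitter = IOCWeightFitter(init_weights=init, **options)
    fitter.fit(dataset)
    return fitter.result_
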
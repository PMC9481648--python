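import numpy as np
import pytest

from copair.oc import CostWeights, CoupledOCModel, OCProblem
from copair.synthetic import StudyDesign, generate_dataset, make_goal_layout
from copair.trajectory import Trajectory


def make_traj(x, y, theta, entity="subject1", normalized=True):
    """Helper: trajectory from coordinate arrays with an implied time axis."""
    x = np.asarray(x, dtype=float)
    t = np.linspace(0.0, 100.0 if normalized else 1.0, x.size)
    return Trajectory(entity, t, x, np.asarray(y, float), np.asarray(theta, float),
                      normalized=normalized)


def random_trajectory(rng, n=60, entity="subject1"):
    """Smooth random planar trajectory for property tests."""
    s = np.linspace(0.0, 1.0, n)
    def field(scale):
        return sum(rng.normal(0, scale / k) * np.sin(k * np.pi * s) for k in range(1, 5))
    x = rng.uniform(-2, 2) + rng.uniform(-3, 3) * s + field(1.0)
    y = rng.uniform(-2, 2) + rng.uniform(-3, 3) * s + field(1.0)
    theta = rng.uniform(-np.pi, np.pi) + rng.uniform(-1, 1) * s + field(0.5)
    return make_traj(x, y, theta, entity)


@pytest.fixture(scope="session")
def goals():
    return make_goal_layout(0)


@pytest.fixture(scope="session")
def reference_weights():
    return CostWeights.reference()


@pytest.fixture(scope="session")
def straight_problem():
    """Both subjects translate 4 m along +x, facing each other throughout."""
    x_start = np.array([-0.9, 0.0, 0.0, 0.9, 0.0, np.pi])
    x_goal = x_start.copy()
    x_goal[[0, 3]] += 4.0
    return OCProblem(x_start, x_goal, T=4.0)


@pytest.fixture(scope="session")
def straight_solution(straight_problem, reference_weights):
    return CoupledOCModel(weights=reference_weights).solve(straight_problem)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_pairs=3, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_dataset(small_design)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(n_pairs=20, seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_design):
    return generate_dataset(default_design)
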
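"""Coupled two-agent optimal-control model of pair locomotion.

Each carrier is a planar *holonomic* agent: its centre of mass moves with
a forward velocity ``v_forw`` along the pelvis heading and an unconstrained
orthogonal velocity ``v_orth`` (side-stepping is free, unlike a unicycle).
The 12-dimensional state stacks, per subject i in {1, 2},

    (x_i, y_i, theta_i, v_forw_i, v_orth_i, omega_i)

and the 6-dimensional control holds the linear and angular accelerations
(u_i1, u_i2, u_i3).  The continuous dynamics per subject are

    dx/dt     = cos(theta) v_forw - sin(theta) v_orth
    dy/dt     = sin(theta) v_forw + cos(theta) v_orth
    dtheta/dt = omega,   dv_forw/dt = u1,  dv_orth/dt = u2,  domega/dt = u3

The running cost combines a time-penalty constant, quadratic control
effort, squared bearing-to-goal errors psi_i, and two exponential barrier
couplings that stand in for the table: chi keeps the inter-subject
distance inside [d_min, d_max] (default 1.6–2.1 m, table length plus arm
reach) and xi_i keeps each subject roughly facing its partner (angular
slack gamma_max, default pi/3).  The terminal cost penalizes goal pose
errors and residual velocities.  The resulting fixed-horizon problem is
solved by an iterative LQR / differential-dynamic-programming scheme with
explicit Euler discretization; the free final time is handled by an outer
grid search over the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from ._angles import wrap_angle
from .markers import normalize_time
from .trajectory import Trajectory

NX = 12  # state dimension (two agents x 6)
NU = 6  # control dimension
D_MIN_DEFAULT = 1.6  # m, minimal inter-subject separation
D_MAX_DEFAULT = 2.1  # m, maximal inter-subject separation
GAMMA_MAX_DEFAULT = np.pi / 3.0  # rad, facing-the-partner slack
NOMINAL_SPEED = 1.2  # m/s, used only to seed the horizon grid

# state index helpers: subject i occupies the slice 6*i .. 6*i+5
IX, IY, ITH, IVF, IVO, IW = range(6)

__all__ = [
    "CostWeights",
    "OCProblem",
    "OCSolution",
    "CoupledOCModel",
    "dynamics",
    "chi_barrier",
    "xi_barrier",
    "heading_error_psi",
    "running_cost",
    "terminal_cost",
    "solve_oc",
    "select_horizon",
    "horizon_cost_profile",
]


@dataclass(frozen=True)
class CostWeights:
    """Nonnegative weights of the running (alpha, 11) and terminal (beta, 4) costs.

    alpha = (time constant, six control-effort weights, two bearing
    weights, separation-barrier weight, facing-barrier weight);
    beta = (terminal position, orientation, linear velocity, angular
    velocity).  The overall scale is arbitrary: multiplying every weight
    by c > 0 leaves the minimizing trajectory unchanged.
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.alpha.shape != (11,) or self.beta.shape != (4,):
            raise ValueError("alpha must have 11 entries and beta 4")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("all cost weights must be nonnegative")
        if not (self.alpha.any() or self.beta.any()):
            raise ValueError("at least one weight must be positive")

    @classmethod
    def reference(cls) -> "CostWeights":
        """The weight set identified on the cohort's scenario-3 averages."""
        return cls(
            alpha=np.array(
                [3.85, 2.29, 10.37, 0.10, 2.7, 8.99, 3.00, 10.42, 1.81e-6, 0.50, 0.03]
            ),
            beta=np.array([19.77, 30.24, 8.77, 9.15]),
        )

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "CostWeights":
        v = np.asarray(v, dtype=float)
        return cls(alpha=v[:11], beta=v[11:15])

    def scaled(self, c: float) -> "CostWeights":
        return CostWeights(self.alpha * c, self.beta * c)

    def normalized(self, total: float = 100.0) -> "CostWeights":
        """Rescale so the weights sum to ``total`` (resolves the scale degeneracy)."""
        s = float(self.alpha.sum() + self.beta.sum())
        return self.scaled(total / s)


@dataclass
class OCProblem:
    """A coupled trajectory-generation problem.

    ``x_start``/``x_goal`` hold the planar poses of the two subjects,
    (x1, y1, theta1, x2, y2, theta2); start velocities are zero.  ``T`` is
    the horizon in seconds, or None for "free" (resolved by
    :func:`select_horizon`).
    """

    x_start: np.ndarray
    x_goal: np.ndarray
    T: Optional[float] = None
    dt: float = 0.05
    d_min: float = D_MIN_DEFAULT
    d_max: float = D_MAX_DEFAULT
    gamma_max: float = GAMMA_MAX_DEFAULT

    def __post_init__(self) -> None:
        self.x_start = np.asarray(self.x_start, dtype=float)
        self.x_goal = np.asarray(self.x_goal, dtype=float)
        if self.x_start.shape != (6,) or self.x_goal.shape != (6,):
            raise ValueError("x_start and x_goal must be pose vectors of length 6")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")
        sep = np.hypot(self.x_start[0] - self.x_start[3], self.x_start[1] - self.x_start[4])
        if not (self.d_min <= sep <= self.d_max):
            raise ValueError(
                f"start separation {sep:.3f} m outside [{self.d_min}, {self.d_max}] m"
            )
        # keep terminal headings on the branch nearest the start headings so the
        # quadratic terminal orientation error acts on the unwrapped signal
        for i, (js, jg) in enumerate(((2, 2), (5, 5))):
            ths, thg = self.x_start[js], self.x_goal[jg]
            self.x_goal[jg] = ths + wrap_angle(thg - ths)

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(NX)
        x0[[IX, IY, ITH]] = self.x_start[:3]
        x0[[6 + IX, 6 + IY, 6 + ITH]] = self.x_start[3:]
        return x0

    def with_horizon(self, T: float) -> "OCProblem":
        return replace(self, x_start=self.x_start.copy(), x_goal=self.x_goal.copy(), T=T)


# ---------------------------------------------------------------------------
# dynamics and cost primitives
# ---------------------------------------------------------------------------


def dynamics(state: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Continuous state derivative of the two coupled holonomic agents."""
    state = np.asarray(state, dtype=float)
    control = np.asarray(control, dtype=float)
    if not (np.all(np.isfinite(state)) and np.all(np.isfinite(control))):
        raise ValueError("dynamics received non-finite state or control")
    dx = np.empty(NX)
    for i in (0, 1):
        s = state[6 * i: 6 * i + 6]
        c, sn = np.cos(s[ITH]), np.sin(s[ITH])
        dx[6 * i + IX] = c * s[IVF] - sn * s[IVO]
        dx[6 * i + IY] = sn * s[IVF] + c * s[IVO]
        dx[6 * i + ITH] = s[IW]
        dx[6 * i + IVF: 6 * i + IW + 1] = control[3 * i: 3 * i + 3]
    return dx


def _separation(state: np.ndarray) -> float:
    return float(np.hypot(state[IX] - state[6 + IX], state[IY] - state[6 + IY]))


def chi_barrier(state: np.ndarray, d_min: float = D_MIN_DEFAULT,
                d_max: float = D_MAX_DEFAULT) -> float:
    """Exponential separation barrier: 0 while d_min < d < d_max, else exp(gap) - 1."""
    if not d_min < d_max:
        raise ValueError("d_min must be below d_max")
    d = _separation(np.asarray(state, dtype=float))
    if d_min < d < d_max:
        return 0.0
    return float(np.expm1(min(abs(d - d_max), abs(d - d_min))))


def xi_barrier(state: np.ndarray, i: int, gamma_max: float = GAMMA_MAX_DEFAULT) -> float:
    """Facing barrier for subject ``i`` (1 or 2).

    gamma_i is the absolute angle between subject i's heading and the
    bearing towards its partner; the barrier is 0 while gamma_i <
    gamma_max, else exp(gamma_i - gamma_max) - 1.
    """
    state = np.asarray(state, dtype=float)
    if i not in (1, 2):
        raise ValueError("subject index must be 1 or 2")
    a, b = (0, 6) if i == 1 else (6, 0)
    dxy = state[[b + IX, b + IY]] - state[[a + IX, a + IY]]
    if np.hypot(*dxy) < 1e-9:
        raise ValueError("subjects are co-located; facing angle undefined")
    gamma = abs(wrap_angle(np.arctan2(dxy[1], dxy[0]) - state[a + ITH]))
    if gamma < gamma_max:
        return 0.0
    return float(np.expm1(gamma - gamma_max))


def heading_error_psi(state: np.ndarray, x_goal: np.ndarray, i: int) -> float:
    """Bearing-to-goal minus heading for subject ``i``, wrapped to (-pi, pi].

    Defined as 0 at the goal point itself, where the bearing is undefined
    and the corresponding cost term should vanish.
    """
    state = np.asarray(state, dtype=float)
    x_goal = np.asarray(x_goal, dtype=float)
    if i not in (1, 2):
        raise ValueError("subject index must be 1 or 2")
    a = 0 if i == 1 else 6
    g = x_goal[0:2] if i == 1 else x_goal[3:5]
    dxy = g - state[[a + IX, a + IY]]
    if np.hypot(*dxy) < 1e-9:
        return 0.0
    return float(wrap_angle(np.arctan2(dxy[1], dxy[0]) - state[a + ITH]))


def running_cost(state: np.ndarray, control: np.ndarray, weights: CostWeights,
                 x_goal: np.ndarray, d_min: float = D_MIN_DEFAULT,
                 d_max: float = D_MAX_DEFAULT,
                 gamma_max: float = GAMMA_MAX_DEFAULT) -> float:
    """Instantaneous running cost phi_r(X, U)."""
    a = weights.alpha
    u = np.asarray(control, dtype=float)
    val = a[0] + float(np.dot(a[1:7], u**2))
    val += a[7] * heading_error_psi(state, x_goal, 1) ** 2
    val += a[8] * heading_error_psi(state, x_goal, 2) ** 2
    val += a[9] * chi_barrier(state, d_min, d_max)
    val += a[10] * (xi_barrier(state, 1, gamma_max) + xi_barrier(state, 2, gamma_max))
    return float(val)


def terminal_cost(state: np.ndarray, weights: CostWeights, x_goal: np.ndarray) -> float:
    """Terminal cost phi_t(X(T)): goal pose errors plus residual velocities."""
    b = weights.beta
    s = np.asarray(state, dtype=float)
    g = np.asarray(x_goal, dtype=float)
    pos_err = ((g[0] - s[IX]) ** 2 + (g[1] - s[IY]) ** 2
               + (g[3] - s[6 + IX]) ** 2 + (g[4] - s[6 + IY]) ** 2)
    ang_err = (g[2] - s[ITH]) ** 2 + (g[5] - s[6 + ITH]) ** 2
    lin_vel = s[IVF] ** 2 + s[IVO] ** 2 + s[6 + IVF] ** 2 + s[6 + IVO] ** 2
    ang_vel = s[IW] ** 2 + s[6 + IW] ** 2
    return float(b[0] * pos_err + b[1] * ang_err + b[2] * lin_vel + b[3] * ang_vel)


# ---------------------------------------------------------------------------
# batched cost/dynamics derivatives for the iLQR sweeps
# ---------------------------------------------------------------------------

_POS_EPS2 = 1e-12  # squared distance below which bearings are treated as undefined


def _batch_dynamics_jacobians(X: np.ndarray, dt: float):
    """Discrete Jacobians fx (K,12,12), fu (K,12,6) of the Euler step."""
    K = X.shape[0]
    A = np.zeros((K, NX, NX))
    for i in (0, 1):
        o = 6 * i
        th, vf, vo = X[:, o + ITH], X[:, o + IVF], X[:, o + IVO]
        c, s = np.cos(th), np.sin(th)
        A[:, o + IX, o + ITH] = -s * vf - c * vo
        A[:, o + IX, o + IVF] = c
        A[:, o + IX, o + IVO] = -s
        A[:, o + IY, o + ITH] = c * vf - s * vo
        A[:, o + IY, o + IVF] = s
        A[:, o + IY, o + IVO] = c
        A[:, o + ITH, o + IW] = 1.0
    fx = np.broadcast_to(np.eye(NX), (K, NX, NX)).copy() + dt * A
    B = np.zeros((NX, NU))
    for i in (0, 1):
        B[6 * i + IVF: 6 * i + IW + 1, 3 * i: 3 * i + 3] = np.eye(3)
    fu = np.broadcast_to(dt * B, (K, NX, NU)).copy()
    return fx, fu


def _psi_terms(X: np.ndarray, x_goal: np.ndarray, i: int):
    """psi values and state-gradients (K,12) for subject i (0-based offset)."""
    K = X.shape[0]
    o = 6 * i
    g = x_goal[0:2] if i == 0 else x_goal[3:5]
    dx = g[0] - X[:, o + IX]
    dy = g[1] - X[:, o + IY]
    rho2 = dx * dx + dy * dy
    ok = rho2 > _POS_EPS2
    psi = np.zeros(K)
    psi[ok] = wrap_angle(np.arctan2(dy[ok], dx[ok]) - X[ok, o + ITH])
    grad = np.zeros((K, NX))
    grad[ok, o + IX] = dy[ok] / rho2[ok]
    grad[ok, o + IY] = -dx[ok] / rho2[ok]
    grad[ok, o + ITH] = -1.0
    return psi, grad


def _chi_terms(X: np.ndarray, d_min: float, d_max: float):
    """chi values, gradients (K,12) and GN direction (K,12) for the separation barrier."""
    K = X.shape[0]
    ddx = X[:, IX] - X[:, 6 + IX]
    ddy = X[:, IY] - X[:, 6 + IY]
    d = np.hypot(ddx, ddy)
    d_safe = np.maximum(d, 1e-9)
    hi = d >= d_max
    lo = d <= d_min
    gap = np.where(hi, d - d_max, np.where(lo, d_min - d, 0.0))
    val = np.where(hi | lo, np.expm1(gap), 0.0)
    sign = np.where(hi, 1.0, np.where(lo, -1.0, 0.0))
    gd = np.zeros((K, NX))  # gradient of d
    gd[:, IX] = ddx / d_safe
    gd[:, IY] = ddy / d_safe
    gd[:, 6 + IX] = -ddx / d_safe
    gd[:, 6 + IY] = -ddy / d_safe
    gg = sign[:, None] * gd  # gradient of the gap where active
    grad = (np.exp(gap) * (hi | lo))[:, None] * gg
    return val, grad, gg, np.exp(gap) * (hi | lo)


def _xi_terms(X: np.ndarray, i: int, gamma_max: float):
    """xi values, gradients and GN pieces for the facing barrier of subject i (0-based)."""
    K = X.shape[0]
    o = 6 * i
    p = 6 * (1 - i)
    dx = X[:, p + IX] - X[:, o + IX]
    dy = X[:, p + IY] - X[:, o + IY]
    rho2 = np.maximum(dx * dx + dy * dy, _POS_EPS2)
    graw = wrap_angle(np.arctan2(dy, dx) - X[:, o + ITH])
    gamma = np.abs(graw)
    act = gamma >= gamma_max
    val = np.where(act, np.expm1(gamma - gamma_max), 0.0)
    sgn = np.sign(graw)
    sgn[sgn == 0] = 1.0
    gb = np.zeros((K, NX))  # gradient of the bearing minus heading
    gb[:, o + IX] = dy / rho2
    gb[:, o + IY] = -dx / rho2
    gb[:, p + IX] = -dy / rho2
    gb[:, p + IY] = dx / rho2
    gb[:, o + ITH] = -1.0
    gg = sgn[:, None] * gb  # gradient of gamma
    scale = np.exp(np.where(act, gamma - gamma_max, 0.0)) * act
    grad = scale[:, None] * gg
    return val, grad, gg, scale


def _stage_cost_derivs(X: np.ndarray, U: np.ndarray, weights: CostWeights,
                       x_goal: np.ndarray, dt: float, d_min: float, d_max: float,
                       gamma_max: float):
    """Batched value/gradient/Hessian of dt * phi_r at each of the K stages.

    Hessians use Gauss-Newton outer products; the barriers use the
    one-sided outside derivative at their kinks.
    """
    a = weights.alpha
    K = X.shape[0]
    l = np.full(K, a[0])
    lx = np.zeros((K, NX))
    lxx = np.zeros((K, NX, NX))
    lu = 2.0 * a[1:7] * U
    luu = np.broadcast_to(np.diag(2.0 * a[1:7]), (K, NU, NU)).copy()
    l += np.sum(a[1:7] * U**2, axis=1)

    for i, w in ((0, a[7]), (1, a[8])):
        if w == 0.0:
            continue
        psi, g = _psi_terms(X, x_goal, i)
        l += w * psi**2
        lx += (2.0 * w * psi)[:, None] * g
        # Gauss-Newton Hessian of w*psi^2: 2w g g^T (the psi * d2psi term is dropped)
        lxx += 2.0 * w * np.einsum("ki,kj->kij", g, g)

    if a[9] > 0.0:
        val, grad, gg, scale = _chi_terms(X, d_min, d_max)
        l += a[9] * val
        lx += a[9] * grad
        lxx += a[9] * np.einsum("k,ki,kj->kij", scale, gg, gg)
    if a[10] > 0.0:
        for i in (0, 1):
            val, grad, gg, scale = _xi_terms(X, i, gamma_max)
            l += a[10] * val
            lx += a[10] * grad
            lxx += a[10] * np.einsum("k,ki,kj->kij", scale, gg, gg)

    return dt * l, dt * lx, dt * lu, dt * lxx, dt * luu


def _terminal_derivs(xT: np.ndarray, weights: CostWeights, x_goal: np.ndarray):
    b = weights.beta
    lx = np.zeros(NX)
    H = np.zeros((NX, NX))
    for i in (0, 1):
        o = 6 * i
        g = x_goal[3 * i: 3 * i + 3]
        lx[o + IX] = -2.0 * b[0] * (g[0] - xT[o + IX])
        lx[o + IY] = -2.0 * b[0] * (g[1] - xT[o + IY])
        lx[o + ITH] = -2.0 * b[1] * (g[2] - xT[o + ITH])
        lx[o + IVF] = 2.0 * b[2] * xT[o + IVF]
        lx[o + IVO] = 2.0 * b[2] * xT[o + IVO]
        lx[o + IW] = 2.0 * b[3] * xT[o + IW]
        H[o + IX, o + IX] = H[o + IY, o + IY] = 2.0 * b[0]
        H[o + ITH, o + ITH] = 2.0 * b[1]
        H[o + IVF, o + IVF] = H[o + IVO, o + IVO] = 2.0 * b[2]
        H[o + IW, o + IW] = 2.0 * b[3]
    return lx, H


# ---------------------------------------------------------------------------
# the iLQR / DDP solver
# ---------------------------------------------------------------------------


class SolverError(RuntimeError):
    """Raised when the trajectory optimizer fails to converge."""

    def __init__(self, message: str, cost_trace=None, states=None):
        super().__init__(message)
        self.cost_trace = cost_trace
        self.states = states


@dataclass
class OCSolution:
    """A solved coupled trajectory plus solver diagnostics."""

    subject1: Trajectory  # time-normalized, N = 500
    subject2: Trajectory
    states: np.ndarray  # (K+1, 12) raw Euler rollout
    controls: np.ndarray  # (K, 6)
    t: np.ndarray  # (K+1,) seconds
    cost: float
    warm_cost: float
    iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def _rollout(x0: np.ndarray, U: np.ndarray, dt: float) -> np.ndarray:
    K = U.shape[0]
    X = np.empty((K + 1, NX))
    X[0] = x0
    for k in range(K):
        X[k + 1] = X[k] + dt * dynamics(X[k], U[k])
    return X


def _total_cost(X: np.ndarray, U: np.ndarray, weights: CostWeights, prob: OCProblem) -> float:
    c = 0.0
    for k in range(U.shape[0]):
        c += prob.dt * running_cost(X[k], U[k], weights, prob.x_goal,
                                    prob.d_min, prob.d_max, prob.gamma_max)
    return c + terminal_cost(X[-1], weights, prob.x_goal)


def _trapezoid_profile(tau: np.ndarray, frac: float = 0.25):
    """Normalized trapezoidal time scaling s(tau) and its derivative on [0, 1]."""
    s = np.empty_like(tau)
    sd = np.empty_like(tau)
    a = frac
    denom = a * (1.0 - a)
    acc = tau < a
    dec = tau > 1.0 - a
    mid = ~(acc | dec)
    s[acc] = tau[acc] ** 2 / (2.0 * denom)
    sd[acc] = tau[acc] / denom
    s[mid] = (tau[mid] - a / 2.0) / (1.0 - a)
    sd[mid] = 1.0 / (1.0 - a)
    s[dec] = 1.0 - (1.0 - tau[dec]) ** 2 / (2.0 * denom)
    sd[dec] = (1.0 - tau[dec]) / denom
    return s, sd


def _warm_start_controls(prob: OCProblem, K: int) -> np.ndarray:
    """Controls reproducing a straight-line pose interpolation with a
    trapezoidal velocity profile (deterministic warm start)."""
    tau = np.arange(K + 1) * prob.dt / (K * prob.dt)
    s, sd = _trapezoid_profile(tau)
    T = K * prob.dt
    V = np.zeros((K + 1, NU))
    for i in (0, 1):
        ps = prob.x_start[3 * i: 3 * i + 2]
        pf = prob.x_goal[3 * i: 3 * i + 2]
        ths, thf = prob.x_start[3 * i + 2], prob.x_goal[3 * i + 2]
        th = ths + s * (thf - ths)
        vx = sd[:, None] * (pf - ps)[None, :] / T
        c, sn = np.cos(th), np.sin(th)
        V[:, 3 * i] = c * vx[:, 0] + sn * vx[:, 1]  # v_forw
        V[:, 3 * i + 1] = -sn * vx[:, 0] + c * vx[:, 1]  # v_orth
        V[:, 3 * i + 2] = sd * (thf - ths) / T  # omega
    return np.diff(V, axis=0) / prob.dt


def _ilqr(prob: OCProblem, weights: CostWeights, U0: np.ndarray, max_iter: int,
          tol: float):
    dt = prob.dt
    x0 = prob.initial_state()
    U = U0.copy()
    X = _rollout(x0, U, dt)
    cost = _total_cost(X, U, weights, prob)
    trace = [cost]
    mu = 1e-6
    mu_max = 1e9
    it = 0
    converged = False
    alphas = 0.5 ** np.arange(7)
    while it < max_iter:
        it += 1
        fx, fu = _batch_dynamics_jacobians(X[:-1], dt)
        l, lx, lu, lxx, luu = _stage_cost_derivs(
            X[:-1], U, weights, prob.x_goal, dt, prob.d_min, prob.d_max, prob.gamma_max
        )
        VxT, VxxT = _terminal_derivs(X[-1], weights, prob.x_goal)

        improved = False
        while mu <= mu_max and not improved:
            # backward pass
            Vx, Vxx = VxT.copy(), VxxT.copy()
            K_gains = np.empty((U.shape[0], NU, NX))
            k_ff = np.empty((U.shape[0], NU))
            ok = True
            for k in range(U.shape[0] - 1, -1, -1):
                Qx = lx[k] + fx[k].T @ Vx
                Qu = lu[k] + fu[k].T @ Vx
                Qxx = lxx[k] + fx[k].T @ Vxx @ fx[k]
                Quu = luu[k] + fu[k].T @ Vxx @ fu[k]
                Qux = fu[k].T @ Vxx @ fx[k]
                Quu_reg = Quu + mu * np.eye(NU)
                try:
                    L = np.linalg.cholesky(Quu_reg)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                rhs = np.column_stack([Qu, Qux])
                sol = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
                k_ff[k] = -sol[:, 0]
                K_gains[k] = -sol[:, 1:]
                Vx = Qx + K_gains[k].T @ Quu @ k_ff[k] + K_gains[k].T @ Qu + Qux.T @ k_ff[k]
                Vxx = Qxx + K_gains[k].T @ Quu @ K_gains[k] + K_gains[k].T @ Qux \
                    + Qux.T @ K_gains[k]
                Vxx = 0.5 * (Vxx + Vxx.T)
            if not ok:
                mu *= 10.0
                continue
            # forward pass with backtracking line search
            for alpha in alphas:
                Xn = np.empty_like(X)
                Un = np.empty_like(U)
                Xn[0] = x0
                for k in range(U.shape[0]):
                    Un[k] = U[k] + alpha * k_ff[k] + K_gains[k] @ (Xn[k] - X[k])
                    Xn[k + 1] = Xn[k] + dt * dynamics(Xn[k], Un[k])
                new_cost = _total_cost(Xn, Un, weights, prob)
                if new_cost < cost:
                    improved = True
                    rel = (cost - new_cost) / max(abs(cost), 1.0)
                    X, U, cost = Xn, Un, new_cost
                    trace.append(cost)
                    mu = max(mu / 10.0, 1e-9)
                    if rel < tol:
                        converged = True
                    break
            if not improved:
                mu *= 10.0
        if mu > mu_max:
            # regularization exhausted with no descending step found: the iterate
            # is stationary to line-search precision
            converged = True
        if converged:
            break
    return X, U, cost, it, converged, trace


def _states_to_trajectories(X: np.ndarray, t: np.ndarray, n_norm: int):
    out = []
    for i, ent in ((0, "subject1"), (1, "subject2")):
        o = 6 * i
        tr = Trajectory(ent, t, X[:, o + IX], X[:, o + IY], X[:, o + ITH])
        out.append(normalize_time(tr, n_norm))
    return out


class CoupledOCModel(BaseEstimator):
    """Generative coupled-carriage trajectory model (scikit-learn style).

    Parameters are the cost weights and solver settings; :meth:`solve`
    produces the locally optimal pair of trajectories for one problem and
    :meth:`predict` maps a list of problems to solutions.  The estimator
    is stateless across calls (no fit is required): it exists so weight
    sets can be cloned, inspected and grid-searched with the standard
    scikit-learn tooling.
    """

    def __init__(self, weights: Optional[CostWeights] = None, dt: float = 0.05,
                 max_iter: int = 500, tol: float = 1e-6, n_norm: int = 500):
        self.weights = weights
        self.dt = dt
        self.max_iter = max_iter
        self.tol = tol
        self.n_norm = n_norm

    def _weights(self) -> CostWeights:
        return self.weights if self.weights is not None else CostWeights.reference()

    def solve(self, problem: OCProblem, warm_controls: Optional[np.ndarray] = None
              ) -> OCSolution:
        if problem.T is None:
            problem = problem.with_horizon(select_horizon(problem, self._weights(),
                                                          dt=self.dt))
        prob = replace(problem, x_start=problem.x_start.copy(),
                       x_goal=problem.x_goal.copy(), dt=self.dt)
        K = max(2, int(round(prob.T / prob.dt)))
        U0 = _warm_start_controls(prob, K)
        w = self._weights()
        warm_X = _rollout(prob.initial_state(), U0, prob.dt)
        warm_cost = _total_cost(warm_X, U0, w, prob)
        if warm_controls is not None and warm_controls.shape == U0.shape:
            cand_X = _rollout(prob.initial_state(), warm_controls, prob.dt)
            if _total_cost(cand_X, warm_controls, w, prob) < warm_cost:
                U0 = warm_controls
        X, U, cost, iters, converged, trace = _ilqr(prob, w, U0, self.max_iter, self.tol)
        if not converged:
            raise SolverError(
                f"trajectory optimizer did not converge in {self.max_iter} iterations "
                f"(last cost {cost:.4g})",
                cost_trace=trace, states=X,
            )
        t = np.arange(K + 1) * prob.dt
        traj1, traj2 = _states_to_trajectories(X, t, self.n_norm)
        term = X[-1]
        diag = {
            "terminal_pos_error": (
                float(np.hypot(prob.x_goal[0] - term[IX], prob.x_goal[1] - term[IY])),
                float(np.hypot(prob.x_goal[3] - term[6 + IX], prob.x_goal[4] - term[6 + IY])),
            ),
            "terminal_angle_error": (
                float(abs(prob.x_goal[2] - term[ITH])),
                float(abs(prob.x_goal[5] - term[6 + ITH])),
            ),
            "chi_values": np.array([chi_barrier(x, prob.d_min, prob.d_max) for x in X]),
            "separation": np.hypot(X[:, IX] - X[:, 6 + IX], X[:, IY] - X[:, 6 + IY]),
            "cost_trace": np.asarray(trace),
            "T": K * prob.dt,
        }
        return OCSolution(traj1, traj2, X, U, t, cost, warm_cost, iters, converged, diag)

    def predict(self, problems) -> list:
        return [self.solve(p) for p in problems]


def solve_oc(problem: OCProblem, weights: CostWeights, dt: Optional[float] = None,
             max_iter: int = 500, tol: float = 1e-6, n_norm: int = 500,
             warm_controls: Optional[np.ndarray] = None) -> OCSolution:
    """Solve one coupled trajectory problem (thin wrapper over CoupledOCModel)."""
    model = CoupledOCModel(weights=weights, dt=dt if dt is not None else problem.dt,
                           max_iter=max_iter, tol=tol, n_norm=n_norm)
    return model.solve(problem, warm_controls=warm_controls)


def _nominal_horizon(problem: OCProblem) -> float:
    d1 = np.hypot(*(problem.x_goal[0:2] - problem.x_start[0:2]))
    d2 = np.hypot(*(problem.x_goal[3:5] - problem.x_start[3:5]))
    return max(0.5 * (d1 + d2), 0.5) / NOMINAL_SPEED


def horizon_cost_profile(problem: OCProblem, weights: CostWeights, grid=None,
                         dt: float = 0.05, max_iter: int = 300, tol: float = 1e-6):
    """Total optimal cost for each candidate horizon on the grid."""
    if grid is None:
        t0 = _nominal_horizon(problem)
        grid = np.arange(0.6 * t0, 1.6 * t0 + 1e-9, 0.5)
        if grid.size == 0:
            grid = np.array([t0])
    model = CoupledOCModel(weights=weights, dt=dt, max_iter=max_iter, tol=tol)
    profile = []
    for T in np.asarray(grid, dtype=float):
        try:
            sol = model.solve(problem.with_horizon(float(T)))
            profile.append((float(T), sol.cost))
        except SolverError:
            continue
    if not profile:
        raise SolverError("all candidate-horizon solves failed")
    return profile


def select_horizon(problem: OCProblem, weights: CostWeights, grid=None,
                   dt: float = 0.05, max_iter: int = 300, tol: float = 1e-6) -> float:
    """Resolve the free final time by grid search over the horizon.

    The grid defaults to 0.6–1.6 times a nominal duration (mean subject
    straight-line distance over a 1.2 m/s casual walking speed) in 0.5 s
    steps; the horizon with minimal total cost wins.
    """
    profile = horizon_cost_profile(problem, weights, grid, dt, max_iter, tol)
    return min(profile, key=lambda p: p[1])[0]
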
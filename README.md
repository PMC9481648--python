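# copair

Modelling and analysis of **pair locomotion during collaborative table
carriage**: two people carry a table between floor positions while their
centre-of-mass (CoM) trajectories — and the table's — are tracked in the
horizontal plane. The package is written for movement scientists and
human-robot-interaction researchers who want to ask, on this kind of
data: do pairs walk differently when only one partner knows the goal?
Are outbound and return paths symmetric? Do pairs place the table in the
configuration that minimizes walking distance? And can the joint
trajectories be generated by a coupled optimal-control (OC) model whose
cost weights are identified by inverse optimal control (IOC)?

## What is inside

- **`copair.markers`** — gait-lab preprocessing: zero-phase low-pass
  Butterworth filtering (4th order, 10 Hz), trial segmentation from the
  table height (lift-off/set-down at 5 mm above the floor), pelvis and
  table planar-pose extraction, time normalization to 0–100 % on
  N = 500 samples.
- **`copair.metrics`** — trajectory similarity and strategy metrics. Two
  time-normalized trajectories X₁, X₂ are compared with

  d_xy(X₁,X₂) = (1/N) Σᵢ ‖(x₁ᵢ,y₁ᵢ) − (x₂ᵢ,y₂ᵢ)‖,
  d_θ(X₁,X₂) = (1/N) Σᵢ |θ₁ᵢ − θ₂ᵢ|,

  plus trajectory averaging, forward/return symmetry (distance to the
  time-reversed return) and configuration-optimality labels based on
  straight-line travelled distances D₁, D₂ and D₁+D₂.
- **`copair.oc`** — the coupled two-agent model. Each carrier is a planar
  holonomic agent with state (x, y, θ, v_forw, v_orth, ω) and
  acceleration controls; the running cost is

  φ_r = α₀ + Σ αₖ uₖ² + α₇ψ₁² + α₈ψ₂² + α₉χ + α₁₀(ξ₁+ξ₂),

  where ψᵢ is the bearing-to-goal error and χ, ξᵢ are exponential
  barriers that keep the carriers 1.6–2.1 m apart and roughly facing each
  other (the table coupling). The terminal cost β₀..β₃ penalizes goal
  pose errors and residual velocities. Problems are solved with an
  iterative LQR / DDP trajectory optimizer (`CoupledOCModel`, a
  scikit-learn-style estimator) with an outer grid search for the free
  final time.
- **`copair.ioc`** — bi-level IOC (`IOCWeightFitter`): Powell search over
  log-weights minimizing the mean of d_xy1 + d_xy2 + ½(d_θ1 + d_θ2)
  between generated and average trajectories, with the return-path role
  switch (Subject 1 ↔ Subject 2). Weights are identifiable only up to a
  global scale.
- **`copair.synthetic`** — a generator that emulates the study design: 20
  pairs × 9 goals (2.7–5.4 m, four requiring a quarter turn) × 3
  scenarios × forward/return = 54 trials per pair, with smooth
  endpoint-pinned perturbations calibrated to 0.20 m / 0.20 rad
  trajectory variability and scenario-dependent travel times.
- **`copair.analysis`** — the nonparametric statistics battery
  (Kruskal–Wallis, Mann–Whitney, Fisher exact, Shapiro–Wilk gate):
  travel-time comparisons, scenario path proximity, configuration
  optimality rates, symmetry, variability and model assessment reports
  as tidy DataFrames.

A thin CLI (`copair preprocess|simulate|generate|analyze|fit`) wraps the
library.

## Worked example

```python
import numpy as np
from copair import CostWeights, OCProblem, solve_oc

# both carriers translate 4 m, holding opposite table ends, facing each other
x_start = np.array([-0.9, 0.0, 0.0, 0.9, 0.0, np.pi])
x_goal = x_start.copy()
x_goal[[0, 3]] += 4.0

sol = solve_oc(OCProblem(x_start, x_goal, T=4.0), CostWeights.reference())
e1, e2 = sol.diagnostics["terminal_pos_error"]
print(f"cost {sol.cost:.3f} (warm start {sol.warm_cost:.3f})")
print(f"terminal miss: {e1:.3f} m / {e2:.3f} m")
print(f"separation barrier active: {np.mean(sol.diagnostics['chi_values'] > 0):.0%}")
```

prints

```
cost 27.682 (warm start 33.142)
terminal miss: 0.072 m / 0.083 m
separation barrier active: 0%
```

The optimizer improves on the straight-line warm start, both carriers
stop within ~8 cm of their goals (soft terminal cost — the model trades
a small miss against effort and time), and the inter-carrier distance
never leaves the 1.6–2.1 m band, so the table coupling is respected
throughout.

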
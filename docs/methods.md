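# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `copair`, in the spirit of a methods appendix.

## Preprocessing

Marker series (nominally 200 Hz) are filtered with a Butterworth low-pass
of design order 4 and 10 Hz cutoff, run forward and backward
(`sosfiltfilt`), i.e. zero phase and the squared magnitude response of
the design. NaN gaps of at most 10 samples are bridged by linear
interpolation before filtering; longer gaps abort the trial with an error
naming the marker — marker loss is surfaced, never imputed.

Trials are segmented on the table height relative to the floor, the
floor being the minimum height over the first 0.5 s (the table rests on
the ground at trial start). A carriage segment runs from the first
sample above 5 mm to the first subsequent sample at or below it; a
complete trial has exactly two segments (forward, return), anything else
is an error listing the candidates.

The subject planar pose is the horizontal centroid of the four pelvis
markers (LASI, RASI, LPSI, RPSI) with heading along the PSIS-midpoint →
ASIS-midpoint vector — the anterior axis of the standard pelvic
anatomical frame. This is a proxy: the exact pelvis-CoM regression used
with the original cohort is not public, but the centroid+heading
construction is translation- and rotation-equivariant, which is the
property every downstream metric relies on. The table pose comes from
three corner markers of the 1.22 × 0.8 m top; the fourth corner is the
parallelogram completion P₁ + P₃ − P₂, with a 5 cm tolerance on edge
lengths.

Headings are unwrapped per trajectory before any interpolation,
averaging or distance: the angular metric d_θ is a plain absolute
difference, which is only meaningful on continuous signals. Time
normalization resamples each segment linearly onto 500 samples of 0–100 %
normalized time, preserving the endpoints exactly.

## Trajectory metrics

d_xy and d_θ are mean pointwise distances between same-N trajectories
(not DTW or Fréchet — sample i is compared with sample i). Averages are
per-sample arithmetic means, including for θ (after unwrapping; a
circular mean is deliberately not used). Symmetry of an out-and-back is
the curve distance between the forward path and the time-reversed
return, with the reversed heading re-anchored to the forward branch so
an irrelevant 2π offset cannot inflate d_θ.

Travelled distance is straight-line start-to-end, not arc length; a
configuration is optimal for Subject i (the pair) if it minimizes Dᵢ
(D₁+D₂) over the two π-rotated table placements, ties counting for both.
Subjects' start/end anchors are the table-centre pose composed with
±0.9 m offsets along the table axis. The offset is deliberately larger
than half the table length (0.61 m): the carriers' CoMs stand beyond the
table ends at arm's reach, and 2 × 0.9 = 1.8 m is the centre of the
admissible separation band of the coupled model. Note a geometric
consequence used in tests: goals on the start axis with unchanged table
orientation have *tied* pair sums (D₁+D₂ identical under both
configurations), so both placements are pair-optimal there.

## The coupled model

Each carrier is planar and holonomic: lateral velocity is a free degree
of freedom, which matters because a carrier walking "backwards" or
side-stepping around a turn cannot be represented by a unicycle. The
12-state dynamics integrate heading-frame velocities; controls are the
six accelerations. Costs:

* α₀ — time penalty (makes shorter horizons attractive);
* α₁..α₆ — quadratic effort per control channel and subject;
* α₇, α₈ — squared bearing-to-goal error ψᵢ, wrapped to (−π, π] and
  defined as 0 at the goal point itself (the bearing degenerates there
  and the term must vanish once the goal is reached);
* α₉ χ — separation barrier: 0 for inter-carrier distance d ∈ (1.6, 2.1) m,
  else exp(min(|d−1.6|, |d−2.1|)) − 1;
* α₁₀ (ξ₁+ξ₂) — facing barriers: 0 while the partner stays within π/3 of
  the carrier's heading, exponential beyond.

The terminal cost penalizes squared goal position errors (β₀), heading
errors (β₁) and residual linear/angular velocities (β₂, β₃). Goal
headings are re-branched to the start headings' unwrapped branch so the
quadratic heading error never sees a spurious 2π.

**Solver.** Explicit Euler at dt = 0.05 s; iterative LQR/DDP with
analytic dynamics Jacobians, Gauss–Newton Hessians for the ψ² and
barrier terms, one-sided *outside* derivatives at the barrier kinks,
Levenberg regularization of Q_uu, and a backtracking line search. The
warm start interpolates poses along straight lines with a trapezoidal
velocity profile (25 % acceleration and deceleration phases) and is
deterministic; accepted iterates only ever decrease the cost, so the
solution cost is bounded by the warm-start cost by construction.
Convergence: relative cost decrease < 1e-6, at most 500 iterations;
exhausting the regularization without a descending step is treated as
stationarity at line-search precision. Halving dt changes the
straight-fixture cost by < 0.1 %, well inside the 2 % consistency
budget.

**Free final time** is resolved by an outer grid search: candidates
0.6–1.6 × T₀ in 0.5 s steps, T₀ = mean subject straight-line distance /
1.2 m s⁻¹ (a casual walking speed), minimal total cost wins. With a
heavy α₀ the grid minimum wins; with α₀ = 0 the cost is non-increasing
in T and the maximum wins — both are property-tested.

## Inverse optimal control

The outer objective is the dataset mean of d_xy1 + d_xy2 + ½(d_θ1+d_θ2);
the ½ puts linear (m) and angular (rad) distances on the same magnitude.
The outer search is Powell over log-weights (nonnegativity by
construction) with initial coordinate steps of 0.3 in log space
(≈ ×1.35): large enough to explore, small enough not to drift along
weakly identified weight combinations. Seeded restarts perturb the
incumbent. Failed inner solves contribute a fixed 10 m-equivalent
penalty so the outer function is total. Each entry's horizon is fixed
once when the entry is built; re-optimizing T inside the bi-level loop
would multiply the cost of every Powell evaluation several-fold for no
measurable benefit on these fixtures. Inner solves are warm-started from
the previous evaluation's controls.

Scaling all weights by c > 0 leaves the inner minimizer — hence the
objective — unchanged, so raw weights are reported alongside a
normalized form and recovery is assessed on unit-sum vectors.
Identifiability beyond scale is *partial*: on noiseless data generated
from known weights, a forward-only entry set leaves the control-effort
weights essentially unconstrained (near-zero misfit with a badly wrong
normalized vector), whereas a mix of straight and quarter-turn goals,
both configurations and both directions pins the vector down to
unit-L1 ≈ 0.2. The recovery experiment therefore uses the diverse
6-entry set, at dt = 0.1 to keep the bi-level loop to a few minutes.
For return paths the subject slots are exchanged before fitting (the
carrier facing the destination on the way back is the one who faced the
start on the way out).

## Synthetic cohort

The generator reproduces the study design, not raw marker data: 20
pairs; 9 goals at 2.7–5.4 m with four quarter-turn goals (2, 4, 6, 8)
and one on-axis quarter-turn goal (2) whose two configurations give each
subject identical distances; 3 scenario blocks run consecutively; every
return is performed with both partners informed, so the three blocks
yield three same-condition returns per goal, and 9 × 2 × 3 = 54 trials
per pair, 1080 trials, 3240 entity trajectories.

Base trajectories are coupled-model solutions (reference weights) per
(goal, configuration, direction), cached; the horizon is the nominal
distance/1.2 m s⁻¹ duration. Inter-pair variability is a smooth random
field per coordinate — 3–6 sinusoids sin(kπs) with 1/k amplitude decay,
zero at both endpoints, so start and goal poses are exact — scaled so
the expected d_xy (d_θ) to the base equals 0.20 m (0.20 rad), with a
per-trial gamma magnitude factor (mean 1, sd 0.5) supplying realistic
dispersion. The table path is the midpoint of the two perturbed carriers
(its variability is therefore ≈ 1/√2 of theirs) plus its own small
0.05 m / 0.05 rad field; heading follows the inter-carrier axis. On the
default cohort this yields subject distance-to-average ≈ 0.19 m and
table ≈ 0.15 m — the measured regime.

Travel times are scenario-dependent normal draws (9.6 ± 2.2 s,
8.9 ± 1.8 s, 8.4 ± 1.5 s) truncated at 3 s; path geometry is
scenario-independent by design (scenarios enter only through timing and
configuration choice). The configuration policy gives, per (scenario,
goal), the probability of choosing the pair-optimal placement: 0.7
everywhere in blocks 1–2 (exploratory), and in block 3 either 1.0
(same-orientation goals) or 0.5 (quarter-turn goals, whose placements
swap which subject walks further). This makes the scenario-3 averaging
cells structurally 13 forward (5 settled + 4 × 2 ambiguous) and 18
return (both configurations reached for every goal across blocks) — the
31-entry fitting layout — and puts the pair-optimal choice rate above
80 %.

Every trial's randomness comes from a SeedSequence keyed by (master
seed, pair, goal, scenario, direction, block, purpose), so any single
trial is independently regenerable and a dataset is bit-reproducible
from its seed.

What the generator does **not** emulate: marker-level noise, gait
oscillations, footsteps, haptic forces, within-trial strategy changes,
or any pair-level idiosyncrasy beyond the smooth fields. Tests passing
on this cohort therefore validate the pipeline's arithmetic, calibration
and statistical behaviour — not claims about real pairs.

## Statistics

A Shapiro–Wilk gate is reported and all inference is nonparametric:
Kruskal–Wallis omnibus tests, Mann–Whitney U pairwise, Fisher's exact
test for categorical dependence (collapsed to 2×2 tables), significance
at p < 0.05. Raw p-values are reported; where many per-goal tests
accumulate (return repeatability) a Benjamini–Hochberg column is added
and labelled as an extension. The within-pair repeatability test
operationalizes "are the three same-condition returns different" as a
Kruskal–Wallis test across the returns' per-sample distances to their
three-trajectory average, restricted to returns sharing the modal
configuration. Scenario-proximity votes count one observation per
pair × goal and only compare trios that ended in the same
configuration. Averaging cells are (goal, configuration, scenario,
direction); averaging never crosses configurations. Box-plot
conventions, where plots are drawn: median, quartiles, whiskers at
Q ± 1.5 IQR.

## Problem sizes and budgets

Defaults used by the test suite and the acceptance script: the full
20-pair cohort for design arithmetic and calibration (≈ 36 cached model
solves); 100-seed travel-time-only replicates for type-I/power
calibration (no trajectory synthesis needed); the 6-entry dt = 0.1
recovery fit with one Powell restart and 300 evaluations. These sizes
were chosen so each experiment completes in minutes while keeping every
statistical conclusion comfortably away from its threshold.

## Known limitations

- The pelvis-CoM proxy and grip-offset geometry are plausible stand-ins,
  not cohort-calibrated values.
- The coupled model couples the carriers only through soft cost barriers;
  with the reference weights the separation barrier can be violated
  during tight quarter-turns (the barrier weights are small). A
  mass-spring table coupling would be a stronger model and is out of
  scope.
- IOC weights are identified only up to scale, and beyond scale only as
  far as the entry geometry excites them; reported raw weights should be
  read through their normalized form.
- The Euler/iLQR solution is a local minimum; different warm starts can
  select different local optima for strongly turning goals.
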
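"""Strategy and variability analysis over a dataset of carriage trials.

The battery mirrors the study's four question groups:

* Q1 — scenario effects: travel-time comparisons, configuration choices,
  and whether the shared-knowledge paths resemble the paths each subject
  chose when leading alone;
* Q2 — forward/return symmetry: distances between each forward path and
  its time-reversed return;
* Q3 — configuration optimality: how often the chosen table placement
  minimizes each subject's (and the pair's) travelled distance;
* Q4 — variability: distances to the cell-average trajectories, their
  trend with goal distance and orientation change, and the within-pair
  repeatability of the three same-condition returns.

Travel times and distances are not normal (a Shapiro–Wilk gate is
reported), so only rank and exact tests are used: Kruskal–Wallis,
Mann–Whitney U and Fisher's exact test, with significance at p < 0.05.
Raw p-values are reported; Benjamini–Hochberg-adjusted columns are an
explicitly labelled extension wherever many per-goal tests accumulate.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import (
    GoalSpec,
    average_trajectory,
    classify_configuration_optimality,
    curve_distance,
    symmetry_distances,
)
from .oc import CostWeights, CoupledOCModel, SolverError
from .trajectory import ENTITIES, TrialRecord

ALPHA = 0.05  # significance level used throughout

__all__ = [
    "travel_time_comparison",
    "scenario_path_proximity",
    "configuration_optimality_rates",
    "symmetry_report",
    "variability_report",
    "model_assessment",
    "normality_gate",
    "trial_frame",
]


def trial_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy metadata table of a dataset (one row per trial)."""
    return pd.DataFrame(
        [
            {
                "pair_id": t.pair_id,
                "goal_id": t.goal_id,
                "scenario": t.scenario,
                "direction": t.direction,
                "config": t.config,
                "block": t.block,
                "travel_time": t.travel_time,
            }
            for t in trials
        ]
    )


def normality_gate(values) -> float:
    """Shapiro–Wilk p-value; small values justify the nonparametric battery."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return float("nan")
    # Shapiro-Wilk is defined for n <= 5000; subsample deterministically beyond
    if values.size > 5000:
        values = values[:: values.size // 5000 + 1]
    return float(stats.shapiro(values).pvalue)


def _safe_kruskal(*groups) -> float:
    groups = [np.asarray(g, float) for g in groups if len(g) > 0]
    if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
        return float("nan")
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return float("nan")


def _safe_mannwhitney(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    except ValueError:
        return float("nan")


# ---------------------------------------------------------------------------
# Q1.1 / Q2.2 — travel times
# ---------------------------------------------------------------------------


def travel_time_comparison(trials: Sequence[TrialRecord], warn=None) -> dict:
    """Per-scenario travel-time summaries with omnibus and pairwise rank tests.

    Scenario groups use forward paths (every return is a scenario-3 path);
    scenario 3 is additionally split into forward and return rows, with a
    rank test of the split.  Scenarios with fewer than 2 trials are
    excluded.
    """
    df = trial_frame(trials)
    fwd = df[df.direction == "forward"]
    groups = {}
    for sc, sub in fwd.groupby("scenario"):
        if len(sub) < 2:
            if warn is not None:
                warn(f"scenario {sc} has fewer than 2 forward trials; excluded")
            continue
        groups[int(sc)] = sub.travel_time.to_numpy()
    returns = df[df.direction == "return"].travel_time.to_numpy()

    rows = [
        {"scenario": sc, "direction": "forward", "n": len(g),
         "mean": float(np.mean(g)), "sd": float(np.std(g, ddof=1))}
        for sc, g in sorted(groups.items())
    ]
    if returns.size >= 2:
        rows.append({"scenario": 3, "direction": "return", "n": returns.size,
                     "mean": float(np.mean(returns)), "sd": float(np.std(returns, ddof=1))})
    summary = pd.DataFrame(rows)

    tests = []
    if len(groups) >= 2:
        tests.append({"test": "kruskal_scenarios", "p": _safe_kruskal(*groups.values())})
        keys = sorted(groups)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                tests.append({"test": f"mannwhitney_{a}_vs_{b}",
                              "p": _safe_mannwhitney(groups[a], groups[b])})
    if 3 in groups and returns.size >= 2:
        tests.append({"test": "mannwhitney_scenario3_forward_vs_return",
                      "p": _safe_mannwhitney(groups[3], returns)})
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["significant"] = tests.p < ALPHA
    return {
        "summary": summary,
        "tests": tests,
        "normality_p": normality_gate(df.travel_time.to_numpy()),
    }


# ---------------------------------------------------------------------------
# Q1.3 — proximity of scenario-3 paths to the single-leader paths
# ---------------------------------------------------------------------------


def scenario_path_proximity(trials: Sequence[TrialRecord], warn=None) -> dict:
    """Which single-leader path each shared-knowledge path is closer to.

    For every pair x goal whose three forward paths ended in the same
    table configuration, the linear distances between the scenario paths
    are computed per entity, and the scenario-3 path votes for the nearer
    of the scenario-1 and scenario-2 paths.  An exact test asks whether
    the votes depend on the subject (one vote per pair x goal).
    """
    index = {}
    for t in trials:
        if t.direction == "forward":
            index[(t.pair_id, t.goal_id, t.scenario)] = t
    rows = []
    pairs_goals = sorted({(p, g) for (p, g, s) in index}, key=lambda k: k)
    for p, g in pairs_goals:
        trio = [index.get((p, g, s)) for s in (1, 2, 3)]
        if any(t is None for t in trio):
            if warn is not None:
                warn(f"pair {p} goal {g}: missing scenario; skipped")
            continue
        if len({t.config for t in trio}) != 1:
            if warn is not None:
                warn(f"pair {p} goal {g}: configurations differ across scenarios; skipped")
            continue
        for ent in ENTITIES:
            x1, x2, x3 = (t.trajectory(ent) for t in trio)
            d13 = curve_distance(x1, x3).d_xy
            d23 = curve_distance(x2, x3).d_xy
            d12 = curve_distance(x1, x2).d_xy
            rows.append({"pair_id": p, "goal_id": g, "entity": ent,
                         "d_1_3": d13, "d_2_3": d23, "d_1_2": d12,
                         "closer_to": 1 if d13 < d23 else 2})
    distances = pd.DataFrame(rows)
    if len(distances) == 0:
        return {"distances": distances, "votes": pd.DataFrame(), "fisher_p": float("nan")}
    votes = (
        distances.groupby(["entity", "closer_to"]).size().unstack(fill_value=0)
        .reindex(columns=[1, 2], fill_value=0)
    )
    votes.columns = ["closer_to_scenario1", "closer_to_scenario2"]
    votes["pct_scenario1"] = 100.0 * votes.closer_to_scenario1 / votes.sum(axis=1)
    table = votes.loc[["subject1", "subject2"],
                      ["closer_to_scenario1", "closer_to_scenario2"]].to_numpy()
    fisher_p = float(stats.fisher_exact(table)[1]) if table.min() >= 0 else float("nan")
    return {"distances": distances, "votes": votes.reset_index(), "fisher_p": fisher_p}


# ---------------------------------------------------------------------------
# Q3 — optimality of the chosen configuration
# ---------------------------------------------------------------------------


def configuration_optimality_rates(trials: Sequence[TrialRecord],
                                   goals: Sequence[GoalSpec]) -> dict:
    """Percentage of forward trials whose configuration was optimal.

    Rates are given per scenario for Subject 1, Subject 2 and the pair
    (both-optimal ties, as on the symmetric goal, count for both
    configurations).  An exact test checks that pair-optimality of the
    choices is not independent of scenario grouping (single-leader blocks
    pooled against the shared-knowledge block).
    """
    goal_map = {g.goal_id: g for g in goals}
    rows = []
    for t in trials:
        if t.direction != "forward":
            continue
        lab = classify_configuration_optimality(goal_map[t.goal_id], t.config)
        rows.append({"pair_id": t.pair_id, "goal_id": t.goal_id, "scenario": t.scenario,
                     "config": t.config,
                     "optimal_subject1": lab.optimal_for_subject1,
                     "optimal_subject2": lab.optimal_for_subject2,
                     "optimal_pair": lab.optimal_for_pair})
    per_trial = pd.DataFrame(rows)
    rates = (
        per_trial.groupby("scenario")[
            ["optimal_subject1", "optimal_subject2", "optimal_pair"]
        ].mean() * 100.0
    ).reset_index()
    overall = per_trial[["optimal_subject1", "optimal_subject2", "optimal_pair"]].mean() * 100.0
    # exact test: pair-optimal vs not, single-leader blocks vs shared-knowledge block
    a = per_trial[per_trial.scenario.isin([1, 2])]
    b = per_trial[per_trial.scenario == 3]
    fisher_p = float("nan")
    if len(a) and len(b):
        table = np.array(
            [[int(a.optimal_pair.sum()), int((~a.optimal_pair).sum())],
             [int(b.optimal_pair.sum()), int((~b.optimal_pair).sum())]]
        )
        fisher_p = float(stats.fisher_exact(table)[1])
    return {"per_trial": per_trial, "rates": rates,
            "overall": overall.to_dict(), "fisher_p": fisher_p}


# ---------------------------------------------------------------------------
# Q2.1 — forward/return symmetry
# ---------------------------------------------------------------------------


def symmetry_report(trials: Sequence[TrialRecord], warn=None) -> dict:
    """Distances between each forward path and its time-reversed return.

    Matched on pair x goal x block; per entity, smaller distances mean a
    more symmetrical out-and-back. Rank tests compare each subject's
    distances against the table's.
    """
    fwd, ret = {}, {}
    for t in trials:
        key = (t.pair_id, t.goal_id, t.block)
        (fwd if t.direction == "forward" else ret)[key] = t
    rows = []
    for key in sorted(fwd):
        if key not in ret:
            if warn is not None:
                warn(f"unmatched forward trial {key}; skipped")
            continue
        for ent in ENTITIES:
            rep = symmetry_distances(fwd[key].trajectory(ent), ret[key].trajectory(ent))
            rows.append({"pair_id": key[0], "goal_id": key[1], "block": key[2],
                         "entity": ent, "d_xy": rep.d_xy, "d_theta": rep.d_theta})
    per_trial = pd.DataFrame(rows)
    if len(per_trial) == 0:
        return {"per_trial": per_trial, "summary": pd.DataFrame(), "tests": pd.DataFrame()}
    summary = (
        per_trial.groupby("entity")[["d_xy", "d_theta"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    tests = []
    tab = per_trial[per_trial.entity == "table"]
    for subj in ("subject1", "subject2"):
        sub = per_trial[per_trial.entity == subj]
        for metric in ("d_xy", "d_theta"):
            tests.append({
                "test": f"mannwhitney_{subj}_vs_table_{metric}",
                "p": _safe_mannwhitney(sub[metric], tab[metric]),
            })
    tests = pd.DataFrame(tests)
    tests["significant"] = tests.p < ALPHA
    return {"per_trial": per_trial, "summary": summary, "tests": tests}


# ---------------------------------------------------------------------------
# Q4 — variability
# ---------------------------------------------------------------------------


def _cell_key(t: TrialRecord):
    return (t.goal_id, t.config, t.scenario, t.direction)


def variability_report(trials: Sequence[TrialRecord],
                       goals: Optional[Sequence[GoalSpec]] = None,
                       warn=None) -> dict:
    """Distances of each trial to its cell-average trajectory, and derived tables.

    Cells are (goal, configuration, scenario, direction) — averaging never
    crosses configurations.  Produces per-scenario summaries, a per-pair
    dispersion test, the distance-vs-goal-distance trend with the
    orientation-change flag, and the within-pair repeatability of the
    three same-condition returns (with a Benjamini–Hochberg column as a
    labelled extension of the raw p-values).
    """
    cells = defaultdict(list)
    for t in trials:
        cells[_cell_key(t)].append(t)

    rows = []
    for key, cell in sorted(cells.items()):
        if len(cell) < 2:
            if warn is not None:
                warn(f"singleton cell {key}; skipped")
            continue
        for ent in ENTITIES:
            avg = average_trajectory([t.trajectory(ent) for t in cell])
            for t in cell:
                rep = curve_distance(t.trajectory(ent), avg)
                rows.append({
                    "goal_id": key[0], "config": key[1], "scenario": key[2],
                    "direction": key[3], "pair_id": t.pair_id, "block": t.block,
                    "entity": ent, "d_xy": rep.d_xy, "d_theta": rep.d_theta,
                    "global_distance": t.meta.get("global_distance", np.nan),
                    "orientation_change": t.meta.get("orientation_change", None),
                })
    per_trial = pd.DataFrame(rows)
    if len(per_trial) == 0:
        raise ValueError("no cell has at least 2 trials; nothing to analyse")

    summary = (
        per_trial.groupby(["scenario", "entity"])[["d_xy", "d_theta"]]
        .agg(["mean", "std"])
        .reset_index()
    )

    # scenario-3 forward vs return comparability of the variability
    tests = []
    s3 = per_trial[per_trial.scenario == 3]
    for ent in ENTITIES:
        sub = s3[s3.entity == ent]
        tests.append({
            "test": f"kruskal_s3_forward_vs_return_{ent}",
            "p": _safe_kruskal(sub[sub.direction == "forward"].d_xy,
                               sub[sub.direction == "return"].d_xy),
        })
    # dispersion across pairs
    for ent in ENTITIES:
        sub = per_trial[per_trial.entity == ent]
        tests.append({
            "test": f"kruskal_across_pairs_{ent}",
            "p": _safe_kruskal(*[g.d_xy.to_numpy() for _, g in sub.groupby("pair_id")]),
        })
    tests = pd.DataFrame(tests)

    trend = (
        per_trial[per_trial.entity != "table"]
        .groupby(["goal_id", "config"])
        .agg(global_distance=("global_distance", "first"),
             orientation_change=("orientation_change", "first"),
             mean_d_xy=("d_xy", "mean"))
        .reset_index()
        .sort_values("global_distance")
    )

    repeat = _return_repeatability(trials, warn)
    return {"per_trial": per_trial, "summary": summary, "tests": tests,
            "trend": trend, "repeatability": repeat}


def _return_repeatability(trials: Sequence[TrialRecord], warn=None) -> pd.DataFrame:
    """Within-pair comparison of the three same-condition returns per goal.

    For one pair x goal, the returns sharing the modal configuration (at
    least 2) are compared: per entity, each return contributes its
    per-sample distances to the group-average trajectory, and a
    Kruskal–Wallis test asks whether the returns differ.
    """
    groups = defaultdict(list)
    for t in trials:
        if t.direction == "return":
            groups[(t.pair_id, t.goal_id)].append(t)
    rows = []
    for (p, g), cand in sorted(groups.items()):
        configs = [t.config for t in cand]
        modal = max(set(configs), key=configs.count)
        reps = [t for t in cand if t.config == modal]
        if len(reps) < 2:
            if warn is not None:
                warn(f"pair {p} goal {g}: fewer than 2 same-configuration returns; skipped")
            continue
        for ent in ENTITIES:
            trajs = [t.trajectory(ent) for t in reps]
            avg = average_trajectory(trajs)
            samples = [np.hypot(tr.x - avg.x, tr.y - avg.y) for tr in trajs]
            rows.append({"pair_id": p, "goal_id": g, "entity": ent,
                         "n_returns": len(reps), "p": _safe_kruskal(*samples)})
    repeat = pd.DataFrame(rows)
    if len(repeat):
        ok = repeat.p.notna()
        repeat["significant"] = repeat.p < ALPHA
        adj = np.full(len(repeat), np.nan)
        if ok.sum() >= 1:
            adj[ok.to_numpy()] = multipletests(repeat.p[ok], method="fdr_bh")[1]
        repeat["p_bh"] = adj  # Benjamini-Hochberg column: extension, not in the protocol
    return repeat


# ---------------------------------------------------------------------------
# model assessment — generated vs average trajectories
# ---------------------------------------------------------------------------


def model_assessment(fit_dataset, weights: CostWeights,
                     measured_distances: Optional[np.ndarray] = None,
                     dt: float = 0.05, max_iter: int = 200) -> dict:
    """Distances between model-generated and average trajectories per entry.

    Reports per-subject linear/angular distances split by direction,
    terminal goal misses (position and heading of the generated paths),
    and — when a sample of measured-to-average distances is supplied — a
    rank test of generated-vs-measured variability (the accuracy gap).
    """
    n = fit_dataset.entries[0].subject1.n
    model = CoupledOCModel(weights=weights, dt=dt, max_iter=max_iter, n_norm=n)
    rows = []
    for entry in fit_dataset:
        try:
            sol = model.solve(entry.problem)
        except SolverError:
            rows.append({"goal_id": entry.goal_id, "config": entry.config,
                         "direction": entry.direction, "subject": "both",
                         "failed": True, "d_xy": np.nan, "d_theta": np.nan,
                         "terminal_miss_pos": np.nan, "terminal_miss_ang": np.nan})
            continue
        term_pos = sol.diagnostics["terminal_pos_error"]
        term_ang = sol.diagnostics["terminal_angle_error"]
        for i, (avg, gen) in enumerate(((entry.subject1, sol.subject1),
                                        (entry.subject2, sol.subject2))):
            rep = curve_distance(avg, gen)
            rows.append({"goal_id": entry.goal_id, "config": entry.config,
                         "direction": entry.direction, "subject": f"subject{i+1}",
                         "failed": False, "d_xy": rep.d_xy, "d_theta": rep.d_theta,
                         "terminal_miss_pos": term_pos[i],
                         "terminal_miss_ang": term_ang[i]})
    per_entry = pd.DataFrame(rows)
    good = per_entry[~per_entry.failed]
    summary = (
        good.groupby("direction")[["d_xy", "d_theta", "terminal_miss_pos"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    gap_p = float("nan")
    if measured_distances is not None and len(good):
        gap_p = _safe_mannwhitney(good.d_xy, np.asarray(measured_distances, float))
    return {"per_entry": per_entry, "summary": summary, "gap_p": gap_p}
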
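"""Statistics battery: travel times, proximity, optimality, symmetry, variability."""

from dataclasses import replace

import numpy as np
import pytest

from copair.analysis import (
    configuration_optimality_rates,
    model_assessment,
    normality_gate,
    scenario_path_proximity,
    symmetry_report,
    travel_time_comparison,
    trial_frame,
    variability_report,
)
from copair.metrics import reverse_trajectory
from copair.synthetic import StudyDesign, build_fit_dataset, generate_dataset
from copair.trajectory import TrialRecord


class TestTravelTimes:
    def test_summary_shape_and_split(self, small_dataset):
        out = travel_time_comparison(small_dataset)
        # one forward row per scenario plus the scenario-3 return row
        assert set(map(tuple, out["summary"][["scenario", "direction"]].to_numpy())) == {
            (1, "forward"), (2, "forward"), (3, "forward"), (3, "return")
        }
        assert {"kruskal_scenarios"} <= set(out["tests"].test)
        assert out["tests"].p.dropna().between(0, 1).all()

    def test_detects_scenario_effect_at_cohort_size(self, goals):
        """A ~1.2 s scenario shift at sd ~1.8 is detectable with 20 pairs."""
        from copair.synthetic import sample_travel_times

        design = StudyDesign(n_pairs=20, goals=list(goals), seed=42)
        df = sample_travel_times(design)
        trials = _records_from_times(df)
        out = travel_time_comparison(trials)
        p = float(out["tests"].set_index("test").loc["kruskal_scenarios", "p"])
        assert p < 0.05

    def test_normality_gate_reported(self, small_dataset):
        out = travel_time_comparison(small_dataset)
        assert 0.0 <= out["normality_p"] <= 1.0


def _records_from_times(df):
    """Lightweight trial records carrying only metadata (for travel-time tests)."""
    from conftest import make_traj

    stub = make_traj(np.zeros(4), np.zeros(4), np.zeros(4))
    records = []
    for row in df.itertuples():
        records.append(TrialRecord(
            pair_id=row.pair_id, goal_id=row.goal_id, scenario=row.scenario,
            direction=row.direction, config="A", block=row.block,
            travel_time=row.travel_time,
            subject1=stub, subject2=replace(stub, entity="subject2"),
            table=replace(stub, entity="table"),
        ))
    return records


class TestScenarioProximity:
    def test_copied_scenario_paths_vote_unanimously(self, small_dataset):
        """If scenario-3 subject-1 paths copy scenario 1, all its votes go there."""
        index = {}
        for t in small_dataset:
            if t.direction == "forward":
                index[(t.pair_id, t.goal_id, t.scenario)] = t
        doctored = []
        for t in small_dataset:
            if t.direction != "forward":
                continue
            if t.scenario == 3:
                s1 = index.get((t.pair_id, t.goal_id, 1))
                if s1 is not None and s1.config == t.config:
                    t = replace(t, subject1=replace(s1.subject1))
            doctored.append(t)
        out = scenario_path_proximity(doctored)
        votes = out["votes"].set_index("entity")
        if votes.loc["subject1"].closer_to_scenario1 + \
           votes.loc["subject1"].closer_to_scenario2 > 0:
            assert votes.loc["subject1", "pct_scenario1"] == pytest.approx(100.0)

    def test_unbiased_generator_splits_votes(self, default_dataset):
        out = scenario_path_proximity(default_dataset)
        votes = out["votes"].set_index("entity")
        for ent in ("subject1", "subject2"):
            pct = votes.loc[ent, "pct_scenario1"]
            assert 20.0 <= pct <= 80.0  # no systematic closeness bias injected
        assert 0.0 <= out["fisher_p"] <= 1.0

    def test_only_matching_configurations_compared(self, small_dataset):
        out = scenario_path_proximity(small_dataset)
        idx = {}
        for t in small_dataset:
            if t.direction == "forward":
                idx[(t.pair_id, t.goal_id, t.scenario)] = t.config
        for row in out["distances"].itertuples():
            cfgs = {idx[(row.pair_id, row.goal_id, s)] for s in (1, 2, 3)}
            assert len(cfgs) == 1


class TestOptimalityRates:
    def test_always_optimal_policy_scores_100(self, goals, reference_weights):
        policy = {(s, g.goal_id): 1.0 for s in (1, 2, 3) for g in goals}
        design = StudyDesign(n_pairs=2, goals=list(goals), seed=1,
                             config_policy=policy)
        trials = generate_dataset(design, reference_weights)
        out = configuration_optimality_rates(trials, goals)
        assert np.allclose(out["rates"].optimal_pair, 100.0)

    def test_uniform_policy_near_chance_excluding_ties(self, goals,
                                                       reference_weights):
        policy = {(s, g.goal_id): 0.5 for s in (1, 2, 3) for g in goals}
        design = StudyDesign(n_pairs=20, goals=list(goals), seed=2,
                             config_policy=policy)
        trials = generate_dataset(design, reference_weights)
        out = configuration_optimality_rates(trials, goals)
        per = out["per_trial"]
        # on-axis goals have tied pair sums (both configurations pair-optimal);
        # among the others a uniform policy is right ~50% of the time
        from copair.metrics import per_subject_distances

        tied = {g.goal_id for g in goals
                if abs(sum(per_subject_distances(g)["A"])
                       - sum(per_subject_distances(g)["B"])) < 1e-9}
        unambig = per[~per.goal_id.isin(tied)]
        rate = unambig.optimal_pair.mean()
        n = len(unambig)
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_tied_goal_counts_for_both_configurations(self, goals,
                                                      small_dataset):
        out = configuration_optimality_rates(small_dataset, goals)
        per = out["per_trial"]
        assert per[per.goal_id == 2].optimal_pair.all()

    def test_rates_and_complements_sum_to_100(self, goals, small_dataset):
        out = configuration_optimality_rates(goals=goals, trials=small_dataset)
        for col in ("optimal_subject1", "optimal_subject2", "optimal_pair"):
            r = out["rates"][col]
            assert ((r >= 0) & (r <= 100)).all()


class TestSymmetry:
    def test_exact_reversals_score_zero(self, small_dataset):
        doctored = []
        for t in small_dataset:
            if t.direction == "forward":
                doctored.append(t)
                doctored.append(replace(
                    t, direction="return", scenario=3,
                    subject1=reverse_trajectory(t.subject1),
                    subject2=reverse_trajectory(t.subject2),
                    table=reverse_trajectory(t.table),
                ))
        out = symmetry_report(doctored)
        assert np.allclose(out["per_trial"].d_xy, 0.0, atol=1e-9)

    def test_report_shape(self, small_dataset):
        out = symmetry_report(small_dataset)
        assert set(out["summary"].entity) == {"subject1", "subject2", "table"}
        assert len(out["tests"]) == 4  # 2 subjects x 2 metrics vs table

    def test_table_more_symmetric_than_subjects(self, default_dataset):
        """The table path inherits averaged-out subject noise, so its
        forward/return asymmetry is smaller; the rank test confirms it."""
        out = symmetry_report(default_dataset)
        med = out["per_trial"].groupby("entity").d_xy.mean()
        assert med["table"] < med[["subject1", "subject2"]].min()
        p = out["tests"].set_index("test").loc[
            "mannwhitney_subject1_vs_table_d_xy", "p"]
        assert p < 0.05


class TestVariability:
    def test_zero_noise_dataset_scores_zero(self, goals, reference_weights):
        design = StudyDesign(n_pairs=2, goals=list(goals), seed=4, noise_xy=0.0,
                             noise_theta=0.0, table_noise_xy=0.0,
                             table_noise_theta=0.0)
        trials = generate_dataset(design, reference_weights)
        out = variability_report(trials, goals)
        assert np.allclose(out["per_trial"].d_xy, 0.0, atol=1e-9)
        assert np.allclose(out["per_trial"].d_theta, 0.0, atol=1e-9)

    def test_default_noise_in_measured_regime(self, default_dataset, goals):
        out = variability_report(default_dataset, goals)
        subj = out["per_trial"][out["per_trial"].entity != "table"]
        assert 0.15 <= subj.d_xy.mean() <= 0.25

    def test_table_below_subjects(self, default_dataset, goals):
        out = variability_report(default_dataset, goals)
        per = out["per_trial"]
        assert per[per.entity == "table"].d_xy.mean() < \
            per[per.entity != "table"].d_xy.mean()

    def test_repeatability_table_has_bh_column(self, small_dataset, goals):
        out = variability_report(small_dataset, goals)
        rep = out["repeatability"]
        assert {"p", "p_bh", "significant"} <= set(rep.columns)
        assert rep.p.dropna().between(0, 1).all()

    def test_trend_carries_orientation_flag(self, small_dataset, goals):
        out = variability_report(small_dataset, goals)
        trend = out["trend"]
        assert trend.orientation_change.notna().all()
        assert (trend.global_distance.between(2.7 - 1e-9, 5.4 + 1e-9)).all()

    def test_all_singleton_cells_is_an_error(self, goals, reference_weights):
        design = StudyDesign(n_pairs=1, goals=list(goals[:1]), seed=9,
                             scenarios=(3,))
        trials = generate_dataset(design, reference_weights)
        fwd = [t for t in trials if t.direction == "forward"]
        with pytest.raises(ValueError, match="at least 2"):
            variability_report(fwd, goals)


class TestModelAssessment:
    def test_self_consistency_at_true_weights(self, small_dataset, small_design,
                                              reference_weights, goals):
        design = replace(small_design, noise_xy=0.0, noise_theta=0.0,
                         table_noise_xy=0.0, table_noise_theta=0.0,
                         goals=list(goals), config_policy=None, n_pairs=1)
        trials = generate_dataset(design, reference_weights)
        ds = build_fit_dataset(trials, design)
        out = model_assessment(ds, reference_weights)
        good = out["per_entry"][~out["per_entry"].failed]
        assert (good.d_xy < 0.01).all()

    def test_perturbed_weights_strictly_positive_distance(self, small_dataset,
                                                          small_design):
        ds = build_fit_dataset(small_dataset, small_design)
        w = replace_weights_scaled()
        out = model_assessment(ds, w)
        good = out["per_entry"][~out["per_entry"].failed]
        assert (good.d_xy > 0).all()
        assert {"terminal_miss_pos", "terminal_miss_ang"} <= set(good.columns)


def replace_weights_scaled():
    from copair.oc import CostWeights

    w = CostWeights.reference()
    v = w.as_vector()
    v[0] *= 4.0  # heavier time pressure bends the solution away
    v[7] *= 0.1
    return CostWeights.from_vector(v)


def test_normality_gate_behaviour():
    rng = np.random.default_rng(0)
    assert normality_gate(rng.normal(size=200)) > 0.01
    assert normality_gate(rng.exponential(size=500) ** 2) < 0.01
    assert np.isnan(normality_gate([1.0, 2.0]))


def test_trial_frame_columns(small_dataset):
    df = trial_frame(small_dataset)
    assert {"pair_id", "goal_id", "scenario", "direction", "config", "block",
            "travel_time"} <= set(df.columns)
    assert len(df) == len(small_dataset)
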
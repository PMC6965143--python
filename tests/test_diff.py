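"""Steady-state diffing and concordance scoring."""

import pytest

from rvdbool import (
    BooleanNetwork,
    ConcordancePattern,
    Not,
    ScenarioConfig,
    Var,
    VariableSpec,
    concordance,
    diff,
    load_packaged_patterns,
    simulate,
)


class TestDiff:
    def test_self_diff_is_all_unchanged(self, study):
        untreated = study.trajectories["untreated"]
        report = diff(untreated, untreated)
        assert all(c.startswith("unchanged") for c in report.classifications)
        assert all(t is None for t in report.first_divergence)

    def test_angioplasty_restores_vegf_and_clears_rarefaction(self, study):
        report = study.diffs["angioplasty_vegf"]
        assert report.classification_of("VEGF") == "activated"
        assert report.classification_of("MVrarefaction") == "inactivated"
        assert report.classification_of("BF") == "activated"

    def test_simvastatin_cannot_clear_ischemia(self, study):
        report = study.diffs["simvastatin"]
        assert report.classification_of("MildIschemia") == "unchanged_active"

    def test_antisymmetry_of_switch_labels(self, study):
        fwd = diff(study.trajectories["eta_blockade"], study.trajectories["untreated"])
        rev = diff(study.trajectories["untreated"], study.trajectories["eta_blockade"])
        swap = {
            "activated": "inactivated",
            "inactivated": "activated",
            "unchanged_active": "unchanged_active",
            "unchanged_inactive": "unchanged_inactive",
        }
        assert tuple(swap[c] for c in fwd.classifications) == rev.classifications

    def test_switched_variables_have_divergence_timepoints(self, study):
        for name, report in study.diffs.items():
            traj = study.trajectories[name]
            bound = len(traj.states) + len(study.trajectories["untreated"].states)
            for c, t in zip(report.classifications, report.first_divergence):
                if c in ("activated", "inactivated"):
                    assert t is not None and 0 <= t <= bound

    def test_divergence_timepoint_is_earliest(self, study):
        report = study.diffs["simvastatin"]
        treated = study.trajectories["simvastatin"]
        untreated = study.trajectories["untreated"]
        i = report.variable_names.index("Simvastatin")
        assert report.first_divergence[i] == 0  # differs already at t=0
        j = report.variable_names.index("ROSscav")
        t = report.first_divergence[j]
        assert treated.state_at(t)[j] != untreated.state_at(t)[j]
        for earlier in range(t):
            assert treated.state_at(earlier)[j] == untreated.state_at(earlier)[j]

    def test_non_fixed_point_input_rejected(self):
        cycle_net = BooleanNetwork(
            [VariableSpec(1, "a"), VariableSpec(2, "b")],
            {1: Not(Var(2)), 2: Var(1)},
        )
        traj = simulate(cycle_net, ScenarioConfig(name="c", initial=(1, 0)))
        with pytest.raises(ValueError, match="fixed point"):
            diff(traj, traj)

    def test_mismatched_networks_rejected(self, study):
        other = BooleanNetwork([VariableSpec(1, "x")], {1: Var(1)})
        traj = simulate(other, ScenarioConfig(name="o", initial=(1,)))
        with pytest.raises(ValueError, match="different networks"):
            diff(traj, study.trajectories["untreated"])


class TestConcordance:
    def test_untreated_pattern_fully_concordant(self, study):
        result = study.concordances["untreated"]
        assert result.match_fraction == 1.0
        assert result.n_stated == 19

    def test_perfect_synthetic_pattern_scores_one(self, study):
        report = study.diffs["simvastatin"]
        pattern = ConcordancePattern(
            scenario_name="simvastatin",
            expected={
                name: "active" if bit else "inactive"
                for name, bit in zip(report.variable_names, report.treated_steady_state)
            },
        )
        assert concordance(report, pattern).match_fraction == 1.0

    def test_empty_pattern_reports_not_applicable(self, study):
        report = study.diffs["untreated"]
        result = concordance(
            report, ConcordancePattern(scenario_name="untreated", expected={})
        )
        assert result.match_fraction is None
        assert result.n_stated == 0

    def test_mismatches_are_reported_not_raised(self, study):
        """Statin arm: rules force VEGF off though the outcome claim says on."""
        result = study.concordances["simvastatin"]
        table = result.table.set_index("variable")
        assert not table.loc["VEGF", "match"]
        assert result.match_fraction < 1.0

    def test_pattern_scenario_must_match_report(self, study):
        pattern = ConcordancePattern(scenario_name="untreated", expected={})
        with pytest.raises(ValueError, match="pattern is for scenario"):
            concordance(study.diffs["simvastatin"], pattern)

    def test_unknown_pattern_variable_rejected(self, study):
        pattern = ConcordancePattern(
            scenario_name="untreated", expected={"NotAVariable": "active"}
        )
        with pytest.raises(KeyError, match="NotAVariable"):
            concordance(study.diffs["untreated"], pattern)

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError, match="active/inactive"):
            ConcordancePattern(scenario_name="s", expected={"BF": "maybe"})

    def test_packaged_patterns_cover_all_scenarios(self, rvd_model):
        patterns = load_packaged_patterns()
        assert set(patterns) == {
            "untreated", "simvastatin", "antioxidant", "eta_blockade",
            "preventive_vegf", "interventional_vegf", "angioplasty_vegf",
        }
        names = set(rvd_model.names)
        for pattern in patterns.values():
            assert set(pattern.expected) <= names
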
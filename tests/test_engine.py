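"""Synchronous stepping, perturbation events and attractor detection."""

import itertools

import pytest

from rvdbool import (
    And,
    BooleanNetwork,
    Not,
    PerturbationEvent,
    ScenarioConfig,
    Var,
    VariableSpec,
    apply_events,
    build_scenario,
    simulate,
    step,
)
from rvdbool.expressions import evaluate

from conftest import active_set
from oracle_rvd import plain_step


@pytest.fixture
def toy_cycle_network():
    """F_a = !b, F_b = a: a period-4 rotation of the 2-bit state space."""
    return BooleanNetwork(
        [VariableSpec(1, "a"), VariableSpec(2, "b")],
        {1: Not(Var(2)), 2: Var(1)},
        name="toy",
    )


class TestStep:
    def test_first_untreated_cycle_shuts_flow_before_ischemia_reacts(self, rvd_model):
        """BF drops at t=1 (stenosis on), but ischemia still reads t=0's flow."""
        t0 = build_scenario("untreated").initial
        t1 = step(rvd_model, t0)
        assert t1[0] == 0  # BF off: stenosis active
        assert t1[1] == 0  # mild ischemia reads the old BF=1, stays off
        assert active_set(t1) == {5, 9, 10, 22}

    def test_step_agrees_with_plain_lambda_oracle_across_state_space_sample(
        self, rvd_model
    ):
        # all 2^8 combinations over a spread of 8 positions, others fixed
        positions = [0, 3, 6, 8, 12, 17, 19, 21]
        for combo in itertools.product((0, 1), repeat=8):
            state = [0] * 24
            for pos, bit in zip(positions, combo):
                state[pos] = bit
            state = tuple(state)
            assert step(rvd_model, state) == plain_step(state)

    def test_all_zero_state_is_absorbing_for_plain_and_rules(self):
        n = BooleanNetwork(
            [VariableSpec(1, "a"), VariableSpec(2, "b")],
            {1: And(Var(1), Var(2)), 2: And(Var(2), Var(1))},
        )
        assert step(n, (0, 0)) == (0, 0)

    def test_length_mismatch_rejected(self, rvd_model):
        with pytest.raises(ValueError, match="24 variables"):
            step(rvd_model, (0, 1))

    def test_compiled_rules_match_interpreter(self, rvd_model):
        compiled = rvd_model.compiled_rules()
        state = build_scenario("untreated").initial
        for idx in range(1, 25):
            assert compiled[idx - 1](state) == evaluate(rvd_model.rules[idx], state)


class TestApplyEvents:
    def test_set_event_fires_only_at_its_timepoint(self):
        events = [PerturbationEvent(timepoint=25, variable=1, value=1)]
        assert apply_events((0, 0), events, 25) == (1, 0)
        assert apply_events((0, 0), events, 24) == (0, 0)
        assert apply_events((0, 0), events, 26) == (0, 0)

    def test_clamp_event_holds_from_its_timepoint(self):
        events = [PerturbationEvent(timepoint=3, variable=2, value=1, mode="clamp")]
        assert apply_events((0, 0), events, 2) == (0, 0)
        assert apply_events((0, 0), events, 3) == (0, 1)
        assert apply_events((0, 0), events, 10) == (0, 1)

    def test_empty_event_list_is_identity(self):
        assert apply_events((1, 0, 1), [], 7) == (1, 0, 1)

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError, match="unknown variable"):
            apply_events((0,), [PerturbationEvent(0, variable=5, value=1)], 0)


class TestSimulate:
    def test_identity_network_fixes_immediately(self):
        n = BooleanNetwork(
            [VariableSpec(1, "a"), VariableSpec(2, "b")],
            {1: Var(1), 2: Var(2)},
        )
        traj = simulate(n, ScenarioConfig(name="s", initial=(1, 0)))
        assert traj.classification == "fixed_point"
        assert traj.transient_length == 0
        assert traj.final_state == (1, 0)

    def test_period_four_cycle_detected_with_period(self, toy_cycle_network):
        traj = simulate(toy_cycle_network, ScenarioConfig(name="s", initial=(1, 0)))
        assert traj.classification == "limit_cycle"
        assert traj.period == 4
        assert traj.states[:5] == ((1, 0), (1, 1), (0, 1), (0, 0), (1, 0))

    def test_every_fixed_point_maps_to_itself(self, rvd_model, study):
        for traj in study.trajectories.values():
            assert traj.classification == "fixed_point"
            assert step(rvd_model, traj.final_state) == traj.final_state

    def test_cycle_reproduces_after_one_period(self, toy_cycle_network):
        traj = simulate(toy_cycle_network, ScenarioConfig(name="s", initial=(1, 0)))
        assert traj.states[traj.transient_length] == traj.states[
            traj.transient_length + traj.period
        ]

    def test_fixed_point_trajectory_ends_with_steady_window(self, untreated_trajectory):
        w = 3  # default steady_window
        tail = untreated_trajectory.states[-w:]
        assert len(set(tail)) == 1

    def test_determinism_bit_for_bit(self, rvd_model):
        a = simulate(rvd_model, build_scenario("angioplasty_vegf"))
        b = simulate(rvd_model, build_scenario("angioplasty_vegf"))
        assert a.states == b.states
        assert a.classification == b.classification

    def test_max_steps_exceeded_is_a_classification(self, toy_cycle_network):
        # window larger than any run the 4-cycle can produce, tiny budget,
        # and cycle detection suppressed by a late no-op event
        scenario = ScenarioConfig(
            name="s",
            initial=(1, 0),
            events=(PerturbationEvent(timepoint=9, variable=1, value=1),),
            max_steps=10,
        )
        traj = simulate(toy_cycle_network, scenario)
        assert traj.classification == "max_steps_exceeded"

    def test_events_before_detection_window_still_fire(self, toy_cycle_network):
        # clamping both variables turns the cycle into a fixed point
        scenario = ScenarioConfig(
            name="s",
            initial=(1, 0),
            events=(
                PerturbationEvent(timepoint=5, variable=1, value=0, mode="clamp"),
                PerturbationEvent(timepoint=5, variable=2, value=0, mode="clamp"),
            ),
        )
        traj = simulate(toy_cycle_network, scenario)
        assert traj.classification == "fixed_point"
        assert traj.final_state == (0, 0)


class TestScenarioConfigValidation:
    def test_steady_window_minimum(self):
        with pytest.raises(ValueError, match="steady_window"):
            ScenarioConfig(name="s", initial=(0,), steady_window=1)

    def test_max_steps_must_exceed_last_event(self):
        with pytest.raises(ValueError, match="max_steps"):
            ScenarioConfig(
                name="s",
                initial=(0,),
                events=(PerturbationEvent(timepoint=300, variable=1, value=1),),
                max_steps=200,
            )

    def test_non_binary_initial_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            ScenarioConfig(name="s", initial=(0, 2))
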
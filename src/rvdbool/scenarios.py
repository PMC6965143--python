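"""The seven packaged RVD simulation scenarios.

Every scenario starts from a quiescent healthy kidney (blood flow, ROS
scavenging, NO and VEGF on, everything else off) with renal artery
stenosis switched on, except the combined angioplasty arm where stenosis
is released mid-run. Initial conditions are recorded as 22-entry
positional vectors (the transcription format of the source model):
positions 1-17 map onto biological variables 1-17, positions 18-22 onto
the intervention switches 20-24, and the late-stage variables 18 (severe
ischemia) and 19 (fibrosis) start at 0 — a mapping uniquely consistent
with all seven scenarios.

The two interventional scenarios switch the *entire* state at timepoint
25: the recorded switch vector replaces every variable (it resets the
biological variables to the quiescent pattern while flipping the
intervention bits), realized here as one ``set`` event per variable.
"""

from __future__ import annotations

from typing import Sequence

from .engine import PerturbationEvent, ScenarioConfig, State

__all__ = [
    "SCENARIO_NAMES",
    "TREATED_SCENARIO_NAMES",
    "build_scenario",
    "expand_positional_vector",
    "positional_vector_events",
]

#: printed-position -> variable-index mapping for the 22-entry vectors
_POSITION_TO_VARIABLE = tuple(range(1, 18)) + tuple(range(20, 25))

_N_VARIABLES = 24

# 22-entry positional initial vectors, one per scenario
_INITIAL_VECTORS: dict[str, tuple[int, ...]] = {
    "untreated":          (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0),
    "simvastatin":        (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0),
    "antioxidant":        (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0),
    "eta_blockade":       (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1),
    "preventive_vegf":    (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0),
    "interventional_vegf": (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0),
    "angioplasty_vegf":   (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0),
}

# full-state switch vectors applied at timepoint 25 (positional format)
_SWITCH_VECTORS: dict[str, tuple[int, ...]] = {
    "interventional_vegf": (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0),
    "angioplasty_vegf":    (1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0),
}

_SWITCH_TIMEPOINT = 25

SCENARIO_NAMES: tuple[str, ...] = tuple(_INITIAL_VECTORS)
TREATED_SCENARIO_NAMES: tuple[str, ...] = tuple(
    n for n in SCENARIO_NAMES if n != "untreated"
)


def expand_positional_vector(vector: Sequence[int]) -> State:
    """Expand a 22-entry positional vector to the 24-variable state."""
    vector = tuple(int(b) for b in vector)
    if len(vector) != len(_POSITION_TO_VARIABLE):
        raise ValueError(
            f"positional vector must have {len(_POSITION_TO_VARIABLE)} entries, "
            f"got {len(vector)}"
        )
    if any(b not in (0, 1) for b in vector):
        raise ValueError("positional vector entries must be 0 or 1")
    state = [0] * _N_VARIABLES
    for pos, var in enumerate(_POSITION_TO_VARIABLE, start=1):
        state[var - 1] = vector[pos - 1]
    return tuple(state)


def positional_vector_events(
    vector: Sequence[int], timepoint: int
) -> tuple[PerturbationEvent, ...]:
    """Events realizing a full-state switch to a positional vector."""
    state = expand_positional_vector(vector)
    return tuple(
        PerturbationEvent(timepoint=timepoint, variable=i, value=state[i - 1])
        for i in range(1, _N_VARIABLES + 1)
    )


def build_scenario(
    name: str, max_steps: int = 200, steady_window: int = 3
) -> ScenarioConfig:
    """Return one of the seven packaged scenarios by name.

    Names: ``untreated``, ``simvastatin``, ``antioxidant``,
    ``eta_blockade``, ``preventive_vegf``, ``interventional_vegf``,
    ``angioplasty_vegf``.
    """
    if name not in _INITIAL_VECTORS:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    events: tuple[PerturbationEvent, ...] = ()
    if name in _SWITCH_VECTORS:
        events = positional_vector_events(_SWITCH_VECTORS[name], _SWITCH_TIMEPOINT)
    return ScenarioConfig(
        name=name,
        initial=expand_positional_vector(_INITIAL_VECTORS[name]),
        events=events,
        max_steps=max_steps,
        steady_window=steady_window,
    )
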
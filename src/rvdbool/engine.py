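"""Synchronous simulation with scheduled perturbations.

At each time cycle every variable is simultaneously replaced by the value
of its update rule evaluated on the *previous* state. Perturbation events
overwrite components of the state at a given timepoint before the next
step is computed; ``set`` events fire once, ``clamp`` events re-apply
from their timepoint onward. Because a deterministic map on a finite
state space must eventually revisit a state, every run terminates in a
fixed point or a limit cycle within at most 2^N post-event steps; the
engine detects both by hashing the full state history.

The timescale is arbitrary (one "cycle" is not a fixed physical
duration); runs therefore continue until the state stops changing for a
configurable number of consecutive cycles (``steady_window``) rather
than for a fixed wall-clock horizon.

Steady-state/cycle detection only engages once all scheduled events have
fired: a trajectory that settles before a scheduled switch must keep
running so the switch can still be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .network import BooleanNetwork

__all__ = [
    "State",
    "PerturbationEvent",
    "ScenarioConfig",
    "Trajectory",
    "step",
    "apply_events",
    "simulate",
]

#: An ordered, immutable 0/1 vector; entry ``i-1`` is variable ``i``.
State = tuple[int, ...]


@dataclass(frozen=True)
class PerturbationEvent:
    """Timed override of one variable.

    ``mode="set"`` overwrites the variable once, at ``timepoint``;
    ``mode="clamp"`` holds the value from ``timepoint`` onward regardless
    of what the update rules compute.
    """

    timepoint: int
    variable: int
    value: int
    mode: Literal["set", "clamp"] = "set"

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError("event timepoint must be >= 0")
        if self.value not in (0, 1):
            raise ValueError(f"event value must be 0 or 1, got {self.value!r}")
        if self.mode not in ("set", "clamp"):
            raise ValueError(f"unknown event mode {self.mode!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """An initial state plus scheduled perturbations and run limits."""

    name: str
    initial: State
    events: tuple[PerturbationEvent, ...] = ()
    max_steps: int = 200
    steady_window: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial", tuple(int(b) for b in self.initial))
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.timepoint))
        )
        if any(b not in (0, 1) for b in self.initial):
            raise ValueError("initial state entries must be 0 or 1")
        if self.steady_window < 2:
            raise ValueError("steady_window must be >= 2")
        if self.events and self.max_steps <= max(e.timepoint for e in self.events):
            raise ValueError("max_steps must exceed the last event timepoint")

    def validate_for(self, network: BooleanNetwork) -> None:
        if len(self.initial) != network.n:
            raise ValueError(
                f"scenario {self.name!r}: initial state has {len(self.initial)} "
                f"entries, network has {network.n} variables"
            )
        for e in self.events:
            network.index_of(e.variable)  # raises KeyError if undeclared

    @property
    def last_event_timepoint(self) -> int:
        return max((e.timepoint for e in self.events), default=0)


@dataclass(frozen=True)
class Trajectory:
    """A simulated state sequence and its terminal behaviour.

    ``states[t]`` is the state at timepoint ``t`` *after* any events due
    at ``t`` have been applied. ``transient_length`` is the first
    timepoint of the attractor (the fixed point's final contiguous run,
    or the first state of the detected cycle).
    """

    scenario_name: str
    variable_names: tuple[str, ...]
    states: tuple[State, ...]
    classification: Literal["fixed_point", "limit_cycle", "max_steps_exceeded"]
    period: int | None = None
    transient_length: int | None = None

    def state_at(self, t: int) -> State:
        """State at timepoint ``t``, extending a fixed point past the end."""
        if t < len(self.states):
            return self.states[t]
        if self.classification == "fixed_point":
            return self.states[-1]
        raise IndexError(
            f"timepoint {t} beyond trajectory of length {len(self.states)} "
            f"({self.classification})"
        )

    @property
    def final_state(self) -> State:
        return self.states[-1]

    @property
    def is_fixed_point(self) -> bool:
        return self.classification == "fixed_point"


def step(network: BooleanNetwork, state: Sequence[int]) -> State:
    """One synchronous update: every rule reads ``state``, all at once."""
    if len(state) != network.n:
        raise ValueError(
            f"state has {len(state)} entries, network has {network.n} variables"
        )
    rules = network.compiled_rules()
    s = tuple(state)
    return tuple(f(s) for f in rules)


def apply_events(
    state: Sequence[int],
    events: Sequence[PerturbationEvent],
    timepoint: int,
    n: int | None = None,
) -> State:
    """Overwrite state components for every event due at ``timepoint``.

    ``set`` events fire when their timepoint matches exactly; ``clamp``
    events fire at and after their timepoint. Returns a new state.
    """
    n = len(state) if n is None else n
    out = list(state)
    for e in events:
        due = e.timepoint == timepoint if e.mode == "set" else e.timepoint <= timepoint
        if due:
            if not 1 <= e.variable <= n:
                raise KeyError(f"event references unknown variable index {e.variable}")
            out[e.variable - 1] = e.value
    return tuple(out)


def simulate(network: BooleanNetwork, scenario: ScenarioConfig) -> Trajectory:
    """Run a scenario until a fixed point or cycle is found.

    Stops with ``fixed_point`` once ``steady_window`` consecutive
    identical states have occurred after the last scheduled event, with
    ``limit_cycle`` (and its period) when a post-event state recurs with
    a gap > 1, and with ``max_steps_exceeded`` otherwise.
    """
    scenario.validate_for(network)
    rules = network.compiled_rules()
    events = scenario.events
    watch_from = scenario.last_event_timepoint

    state = apply_events(scenario.initial, events, 0, network.n)
    states: list[State] = [state]
    seen: dict[State, int] = {}
    classification: str = "max_steps_exceeded"
    period: int | None = None
    transient: int | None = None
    run = 1  # length of the current tail of identical states

    for t in range(len(states) - 1, scenario.max_steps):
        if t >= watch_from:
            if run >= scenario.steady_window:
                classification = "fixed_point"
                period = 1
                break
            if state in seen:
                gap = t - seen[state]
                # gap < run means the recurrence lies inside the current
                # tail of identical states — a fixed point building up its
                # steady window, not a cycle
                if gap > 1 and gap >= run:
                    classification = "limit_cycle"
                    period = gap
                    transient = seen[state]
                    break
            else:
                seen[state] = t
        nxt = tuple(f(state) for f in rules)
        nxt = apply_events(nxt, events, t + 1, network.n)
        states.append(nxt)
        run = run + 1 if nxt == state else 1
        state = nxt

    if classification == "fixed_point":
        # first timepoint of the final contiguous run of the fixed point
        fp = states[-1]
        t0 = len(states) - 1
        while t0 > 0 and states[t0 - 1] == fp:
            t0 -= 1
        transient = t0

    return Trajectory(
        scenario_name=scenario.name,
        variable_names=network.names,
        states=tuple(states),
        classification=classification,  # type: ignore[arg-type]
        period=period,
        transient_length=transient,
    )
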
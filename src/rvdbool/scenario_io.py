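"""Scenario config files (YAML) and trajectory tables (TSV).

Scenario files address variables by NAME, never by position::

    name: my_scenario
    initial:            # unlisted variables start at 0
      BF: 1
      RAS: 1
    events:
      - timepoint: 25
        set: {VEGFadmin: 1, RAS: 0}
    max_steps: 200
    steady_window: 3

For fidelity to transcribed source models, ``initial_vector`` /
``vector`` keys accept the 22-entry positional form instead of named
assignments (see :mod:`rvdbool.scenarios` for the position mapping).

Trajectory tables are TSV: one row per variable (name + group), one
column per timepoint, cells 0/1, and a footer row carrying the terminal
classification so a table is self-describing.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

from .engine import PerturbationEvent, ScenarioConfig, Trajectory
from .network import BooleanNetwork
from .scenarios import expand_positional_vector, positional_vector_events

__all__ = [
    "read_scenario",
    "write_scenario",
    "write_trajectory",
    "read_trajectory_states",
]

_FOOTER = "_terminal_"


def read_scenario(path, network: BooleanNetwork) -> ScenarioConfig:
    """Load a scenario config and resolve variable names against ``network``."""
    path = Path(path)
    try:
        # BaseLoader keeps every scalar a string: variable names like "NO"
        # must never be coerced to YAML booleans
        raw = yaml.load(path.read_text(encoding="utf-8"), Loader=yaml.BaseLoader)
    except OSError as exc:
        raise OSError(f"cannot read scenario file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path}: expected a mapping at top level")

    name = raw.get("name", path.stem)

    if "initial_vector" in raw:
        initial = expand_positional_vector(raw["initial_vector"])
    else:
        state = [0] * network.n
        for var, value in (raw.get("initial") or {}).items():
            state[network.index_of(var) - 1] = int(value)
        initial = tuple(state)

    events: list[PerturbationEvent] = []
    for entry in raw.get("events") or []:
        t = int(entry["timepoint"])
        mode = entry.get("mode", "set")
        if "vector" in entry:
            if mode != "set":
                raise ValueError(f"scenario file {path}: vector events must be mode=set")
            events.extend(positional_vector_events(entry["vector"], t))
        else:
            for var, value in entry["set"].items():
                events.append(
                    PerturbationEvent(
                        timepoint=t,
                        variable=network.index_of(var),
                        value=int(value),
                        mode=mode,
                    )
                )

    scenario = ScenarioConfig(
        name=name,
        initial=initial,
        events=tuple(events),
        max_steps=int(raw.get("max_steps", 200)),
        steady_window=int(raw.get("steady_window", 3)),
    )
    scenario.validate_for(network)
    return scenario


def write_scenario(scenario: ScenarioConfig, network: BooleanNetwork, path) -> None:
    """Write a scenario config with named assignments (canonical form)."""
    doc: dict = {
        "name": scenario.name,
        "initial": {
            network.names[i]: 1 for i, b in enumerate(scenario.initial) if b
        },
        "max_steps": scenario.max_steps,
        "steady_window": scenario.steady_window,
    }
    by_time: dict[tuple[int, str], dict[str, int]] = {}
    for e in scenario.events:
        by_time.setdefault((e.timepoint, e.mode), {})[
            network.names[e.variable - 1]
        ] = e.value
    if by_time:
        doc["events"] = [
            {"timepoint": t, "mode": mode, "set": assignments}
            for (t, mode), assignments in sorted(by_time.items())
        ]
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=False),
        encoding="utf-8",
    )


def write_trajectory(trajectory: Trajectory, network: BooleanNetwork, path) -> None:
    """Export a trajectory as a variables x timepoints TSV table."""
    path = Path(path)
    n_t = len(trajectory.states)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variable", "group"] + [f"t{t}" for t in range(n_t)])
        for i, name in enumerate(trajectory.variable_names):
            group = network.variable(name).group
            w.writerow([name, group] + [trajectory.states[t][i] for t in range(n_t)])
        terminal = trajectory.classification
        if trajectory.classification == "limit_cycle":
            terminal += f" period={trajectory.period}"
        if trajectory.transient_length is not None:
            terminal += f" transient={trajectory.transient_length}"
        w.writerow([_FOOTER, terminal] + [""] * n_t)


def read_trajectory_states(path) -> tuple[tuple[str, ...], tuple[tuple[int, ...], ...], str]:
    """Re-import a trajectory TSV.

    Returns ``(variable_names, states, terminal_description)``; the state
    sequence reproduces the exported one exactly.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0][:2] != ["variable", "group"]:
        raise ValueError(f"{path}: not a trajectory table")
    names: list[str] = []
    per_var: list[list[int]] = []
    terminal = ""
    for row in rows[1:]:
        if row[0] == _FOOTER:
            terminal = row[1]
            continue
        names.append(row[0])
        per_var.append([int(c) for c in row[2:] if c != ""])
    states = tuple(zip(*per_var)) if per_var else ()
    return tuple(names), tuple(tuple(s) for s in states), terminal
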
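"""Treated-vs-reference steady-state comparison and concordance scoring.

``diff`` classifies every variable by comparing the fixed points of a
treated and a reference trajectory:

* ``activated`` — off in the reference steady state, on in the treated;
* ``inactivated`` — on in the reference, off in the treated;
* ``unchanged_active`` / ``unchanged_inactive`` — same in both.

``concordance`` scores a simulated steady state against a qualitative
expectation pattern (per-variable active/inactive for the subset of
variables an outcome statement covers); mismatches are reported as data,
never raised, because disagreement between a transcribed rule set and a
narrative outcome claim is itself a result worth surfacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .engine import State, Trajectory

__all__ = [
    "DiffReport",
    "ConcordancePattern",
    "ConcordanceResult",
    "diff",
    "concordance",
    "load_packaged_patterns",
]

Classification = Literal[
    "activated", "inactivated", "unchanged_active", "unchanged_inactive"
]


@dataclass(frozen=True)
class DiffReport:
    """Per-variable steady-state classification of treated vs reference."""

    treated_name: str
    reference_name: str
    variable_names: tuple[str, ...]
    treated_steady_state: State
    reference_steady_state: State
    classifications: tuple[Classification, ...]
    #: earliest timepoint at which each variable's trajectories differ
    #: (None when the two trajectories agree at every timepoint)
    first_divergence: tuple[int | None, ...]

    def classification_of(self, name: str) -> Classification:
        return self.classifications[self.variable_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_names,
                "reference": self.reference_steady_state,
                "treated": self.treated_steady_state,
                "classification": self.classifications,
                "first_divergence": [
                    "" if t is None else t for t in self.first_divergence
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConcordancePattern:
    """Expected terminal status for the variables a claim covers.

    ``expected`` maps variable name -> "active" | "inactive"; variables
    absent from the mapping are unstated and excluded from scoring.
    ``basis`` records, per variable, a short note on where the
    expectation comes from.
    """

    scenario_name: str
    expected: Mapping[str, str]
    basis: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.expected.values()} - {"active", "inactive"}
        if bad:
            raise ValueError(f"expected statuses must be active/inactive, got {bad}")


@dataclass(frozen=True)
class ConcordanceResult:
    scenario_name: str
    table: pd.DataFrame  # variable, expected, simulated, match
    #: matches / stated variables, or None when the pattern states nothing
    match_fraction: float | None

    @property
    def n_stated(self) -> int:
        return len(self.table)


def diff(treated: Trajectory, reference: Trajectory) -> DiffReport:
    """Classify every variable's steady state in ``treated`` vs ``reference``.

    Both trajectories must have ended in a fixed point; a limit cycle has
    no single steady state to compare (re-run with the cycle resolved,
    e.g. by extending ``max_steps`` or adjusting the scenario).
    """
    if treated.variable_names != reference.variable_names:
        raise ValueError(
            "trajectories come from different networks or variable orders"
        )
    for traj in (treated, reference):
        if not traj.is_fixed_point:
            raise ValueError(
                f"trajectory {traj.scenario_name!r} ended in "
                f"{traj.classification}, not a fixed point; steady-state diff "
                "is only defined for fixed points"
            )
    t_ss, r_ss = treated.final_state, reference.final_state
    classes: list[Classification] = []
    for tv, rv in zip(t_ss, r_ss):
        if rv == 0 and tv == 1:
            classes.append("activated")
        elif rv == 1 and tv == 0:
            classes.append("inactivated")
        else:
            classes.append("unchanged_active" if tv == 1 else "unchanged_inactive")

    horizon = max(len(treated.states), len(reference.states))
    divergence: list[int | None] = []
    for i in range(len(t_ss)):
        first: int | None = None
        for t in range(horizon):
            if treated.state_at(t)[i] != reference.state_at(t)[i]:
                first = t
                break
        divergence.append(first)

    return DiffReport(
        treated_name=treated.scenario_name,
        reference_name=reference.scenario_name,
        variable_names=treated.variable_names,
        treated_steady_state=t_ss,
        reference_steady_state=r_ss,
        classifications=tuple(classes),
        first_divergence=tuple(divergence),
    )


def concordance(report: DiffReport, pattern: ConcordancePattern) -> ConcordanceResult:
    """Score a simulated steady state against an expectation pattern.

    The treated steady state of ``report`` is compared with the pattern;
    the match fraction is matches / stated variables (``None`` when the
    pattern states nothing).
    """
    if pattern.scenario_name != report.treated_name:
        raise ValueError(
            f"pattern is for scenario {pattern.scenario_name!r}, report is for "
            f"{report.treated_name!r}"
        )
    unknown = set(pattern.expected) - set(report.variable_names)
    if unknown:
        raise KeyError(
            f"pattern references unknown variables: {sorted(unknown)}"
        )
    rows = []
    for name in report.variable_names:  # keep network order
        if name not in pattern.expected:
            continue
        expected = pattern.expected[name]
        simulated = (
            "active"
            if report.treated_steady_state[report.variable_names.index(name)]
            else "inactive"
        )
        rows.append(
            {
                "variable": name,
                "expected": expected,
                "simulated": simulated,
                "match": expected == simulated,
                "basis": (pattern.basis or {}).get(name, ""),
            }
        )
    table = pd.DataFrame(rows, columns=["variable", "expected", "simulated", "match", "basis"])
    fraction = float(table["match"].mean()) if len(table) else None
    return ConcordanceResult(
        scenario_name=pattern.scenario_name, table=table, match_fraction=fraction
    )


def load_packaged_patterns() -> dict[str, ConcordancePattern]:
    """Load the packaged expectation patterns for the seven scenarios.

    The patterns live in an editable YAML fixture so the transcription
    of each outcome claim can be audited and amended without touching
    code.
    """
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("rvdbool")
        .joinpath("data/concordance.yaml")
        .read_text(encoding="utf-8")
    )
    raw = yaml.safe_load(text)
    return {
        name: ConcordancePattern(
            scenario_name=name,
            expected=entry["expected"],
            basis=entry.get("basis", {}),
        )
        for name, entry in raw.items()
    }
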
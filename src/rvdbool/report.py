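"""One-call study report: all packaged scenarios, diffs and concordance."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diff import ConcordanceResult, DiffReport, concordance, diff, load_packaged_patterns
from .engine import Trajectory, simulate
from .network import BooleanNetwork
from .rvd import build_rvd_model
from .scenarios import SCENARIO_NAMES, TREATED_SCENARIO_NAMES, build_scenario
from .scenario_io import write_trajectory

__all__ = ["StudyReport", "run_study", "write_study"]


class StudyReport:
    """Trajectories, treated-vs-untreated diffs and concordance scores."""

    def __init__(
        self,
        network: BooleanNetwork,
        trajectories: dict[str, Trajectory],
        diffs: dict[str, DiffReport],
        concordances: dict[str, ConcordanceResult],
    ):
        self.network = network
        self.trajectories = trajectories
        self.diffs = diffs
        self.concordances = concordances

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.trajectories:
            traj = self.trajectories[name]
            conc = self.concordances.get(name)
            rows.append(
                {
                    "scenario": name,
                    "terminal": traj.classification,
                    "transient": traj.transient_length,
                    "n_stated": conc.n_stated if conc else 0,
                    "n_matched": int(conc.table["match"].sum()) if conc else 0,
                    "concordance": (
                        round(conc.match_fraction, 4)
                        if conc and conc.match_fraction is not None
                        else ""
                    ),
                }
            )
        return pd.DataFrame(rows)


def run_study(
    variant: str | None = None,
    max_steps: int = 200,
    steady_window: int = 3,
) -> StudyReport:
    """Simulate the seven packaged scenarios and score them.

    Every treated scenario is diffed against untreated; the untreated
    scenario is diffed against itself so its concordance can be scored
    the same way.
    """
    network = build_rvd_model(variant)
    patterns = load_packaged_patterns()
    trajectories = {
        name: simulate(network, build_scenario(name, max_steps, steady_window))
        for name in SCENARIO_NAMES
    }
    reference = trajectories["untreated"]
    diffs = {
        name: diff(trajectories[name], reference) for name in SCENARIO_NAMES
    }
    concordances = {
        name: concordance(diffs[name], patterns[name])
        for name in SCENARIO_NAMES
        if name in patterns
    }
    return StudyReport(network, trajectories, diffs, concordances)


def write_study(report: StudyReport, out_dir) -> list[Path]:
    """Write trajectory, diff and concordance tables under ``out_dir``.

    Emits one trajectory TSV per scenario, one diff TSV per treated
    scenario, one concordance TSV per scored scenario, and a
    ``summary.tsv`` overview. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, traj in report.trajectories.items():
        p = out / f"trajectory_{name}.tsv"
        write_trajectory(traj, report.network, p)
        written.append(p)
    for name in TREATED_SCENARIO_NAMES:
        p = out / f"diff_{name}_vs_untreated.tsv"
        report.diffs[name].to_tsv(p)
        written.append(p)
    for name, conc in report.concordances.items():
        p = out / f"concordance_{name}.tsv"
        conc.table.to_csv(p, sep="\t", index=False)
        written.append(p)
    p = out / "summary.tsv"
    report.summary_frame().to_csv(p, sep="\t", index=False)
    written.append(p)
    return written
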
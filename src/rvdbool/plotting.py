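"""Optional activity-heatmap rendering of trajectories and diffs."""

from __future__ import annotations

from .diff import DiffReport
from .engine import Trajectory

__all__ = ["activity_heatmap", "diff_heatmap"]


def activity_heatmap(trajectory: Trajectory, ax=None, cmap=("0.85", "tab:green")):
    """Variables x timepoints heatmap, active cells coloured.

    Returns the matplotlib Axes. Matplotlib is imported lazily so the
    simulation stack stays importable on display-free hosts.
    """
    import matplotlib
    from matplotlib.colors import ListedColormap
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, len(trajectory.states) * 0.25),
                     max(3, len(trajectory.variable_names) * 0.25))
        )
    data = np.array(trajectory.states).T  # variables x timepoints
    ax.imshow(data, aspect="auto", cmap=ListedColormap(list(cmap)), vmin=0, vmax=1)
    ax.set_yticks(range(len(trajectory.variable_names)))
    ax.set_yticklabels(trajectory.variable_names, fontsize=7)
    ax.set_xlabel("timepoint (arbitrary cycles)")
    ax.set_title(trajectory.scenario_name)
    return ax


def diff_heatmap(report: DiffReport, ax=None):
    """One-column heatmap of the diff classification per variable.

    Activated variables plot positive (blue), inactivated negative (red),
    unchanged neutral.
    """
    from matplotlib.colors import ListedColormap
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(2.5, max(3, len(report.variable_names) * 0.25)))
    code = {"inactivated": 0, "unchanged_inactive": 1, "unchanged_active": 1,
            "activated": 2}
    data = np.array([[code[c] for c in report.classifications]]).T
    ax.imshow(
        data, aspect="auto",
        cmap=ListedColormap(["tab:red", "0.85", "tab:blue"]), vmin=0, vmax=2,
    )
    ax.set_yticks(range(len(report.variable_names)))
    ax.set_yticklabels(report.variable_names, fontsize=7)
    ax.set_xticks([0])
    ax.set_xticklabels([f"{report.treated_name}\nvs {report.reference_name}"], fontsize=7)
    return ax
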
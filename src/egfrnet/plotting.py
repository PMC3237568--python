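"""Optional, headless-safe plotting of trajectories and sensitivity tables.

Acceptance and reporting run on CSV/JSON; these figures are a convenience.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import Trajectory
from .sensitivity import SensitivityTable

__all__ = ["plot_readouts", "plot_sensitivity"]


def plot_readouts(trajectory: Trajectory, readouts=("p-ERK", "p-AKT", "p-p38"),
                  ax=None, logy: bool = False):
    """Readout time courses on one axis; returns the matplotlib Axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name in readouts:
        ax.plot(trajectory.times, trajectory.readout(name), label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (nM)")
    if logy:
        ax.set_yscale("log")
    ax.legend(frameon=False)
    return ax


def plot_sensitivity(table: SensitivityTable, output: str, ax=None,
                     top: int | None = None):
    """Horizontal bar chart of S per species for one readout."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    sub = table.entries[table.entries.output == output]
    if sub.empty:
        raise KeyError(f"output {output!r} not in table")
    sub = sub.reindex(sub.S.abs().sort_values(ascending=True).index)
    if top is not None:
        sub = sub.tail(top)
    ax.barh(sub.species, sub.S)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(f"normalized time-integrated sensitivity of {output}")
    return ax
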
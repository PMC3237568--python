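"""Normalized time-integrated sensitivity of readout totals to species
initial amounts.

For an output readout x and a species y with nonzero initial amount, the
sensitivity is the elasticity-style central finite difference

    S = [ (A+ - A-) / A0 ] / (2 delta),

where A0 is the time integral of the readout over the scenario window and
A± are the same integral with y's initial amount scaled by (1 ± delta).
Each perturbed system is re-equilibrated before stimulation, so S measures
the response of the whole (basal + stimulated) system to a change in total
protein abundance.  S is dimensionless and invariant to rescaling
concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import Scenario, Trajectory, simulate
from .network import Model

__all__ = [
    "SensitivityTable",
    "integrated_response",
    "normalized_sensitivity",
    "sensitivity_scan",
    "rank_sensitivities",
]


@dataclass
class SensitivityTable:
    """One row per (output readout, perturbed species) pair."""

    entries: pd.DataFrame          # columns: output, species, S
    delta_fraction: float
    window: tuple[float, float]
    scenario_id: str = ""
    missing: list[str] | None = None   # species whose perturbed run failed

    def to_frame(self) -> pd.DataFrame:
        df = self.entries.copy()
        df["delta"] = self.delta_fraction
        df["window_start"], df["window_end"] = self.window
        return df

    def value(self, output: str, species: str) -> float:
        rows = self.entries[(self.entries.output == output)
                            & (self.entries.species == species)]
        if rows.empty:
            raise KeyError((output, species))
        return float(rows.S.iloc[0])


def integrated_response(trajectory: Trajectory, readout: str,
                        window: tuple[float, float] | None = None) -> float:
    """Trapezoidal time integral of a readout (nM·min)."""
    t = trajectory.times
    y = trajectory.readout(readout)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    return float(np.trapezoid(y, t))


def _perturb(model: Model, species: str, factor: float) -> Model:
    out_species = []
    for s in model.species:
        if s.name == species:
            s = replace(s, initial_amount=s.initial_amount * factor)
        out_species.append(s)
    return Model(out_species, list(model.reactions), dict(model.metadata))


def normalized_sensitivity(model: Model, scenario: Scenario, output: str,
                           input_species: str,
                           delta_fraction: float = 0.1) -> float:
    """Normalized time-integrated sensitivity of one output to one species."""
    if not 0.0 < delta_fraction <= 0.5:
        raise ValueError("delta_fraction must lie in (0, 0.5]")
    if model.get_species(input_species).initial_amount <= 0:
        raise ValueError(f"{input_species!r} has zero initial amount")
    a0 = integrated_response(simulate(model, scenario), output)
    if a0 == 0:
        raise ZeroDivisionError(f"unperturbed integral of {output} is zero")
    a_up = integrated_response(
        simulate(_perturb(model, input_species, 1.0 + delta_fraction), scenario), output)
    a_dn = integrated_response(
        simulate(_perturb(model, input_species, 1.0 - delta_fraction), scenario), output)
    return ((a_up - a_dn) / a0) / (2.0 * delta_fraction)


def sensitivity_scan(model: Model, scenario: Scenario,
                     outputs: list[str] | None = None,
                     delta_fraction: float = 0.1,
                     species: list[str] | None = None) -> SensitivityTable:
    """Full sensitivity table over every nonzero-initial species.

    The two perturbed simulations per species are shared across outputs, so
    a scan over all three readouts costs 2 n + 1 simulations.
    """
    outputs = outputs or ["p-ERK", "p-AKT", "p-p38"]
    base = simulate(model, scenario)
    for out in outputs:
        if out not in base.readouts.columns:
            raise KeyError(f"unknown readout {out!r}")
    a0 = {out: integrated_response(base, out) for out in outputs}
    targets = species or model.nonzero_initial_species()
    rows, missing = [], []
    for sp in targets:
        try:
            up = simulate(_perturb(model, sp, 1.0 + delta_fraction), scenario)
            dn = simulate(_perturb(model, sp, 1.0 - delta_fraction), scenario)
        except Exception:
            missing.append(sp)
            continue
        for out in outputs:
            if a0[out] == 0:
                continue
            s = ((integrated_response(up, out) - integrated_response(dn, out))
                 / a0[out]) / (2.0 * delta_fraction)
            rows.append({"output": out, "species": sp, "S": s})
    entries = pd.DataFrame(rows, columns=["output", "species", "S"])
    return SensitivityTable(entries, delta_fraction,
                            (float(base.times[0]), float(base.times[-1])),
                            missing=missing or None)


def rank_sensitivities(table: SensitivityTable, output: str,
                       exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """Species ranked by |S| (descending; ties alphabetical) for one output.

    ``exclude`` drops species from the ranking — used to remove the trivial
    entries (the readout's own precursor and the stimulus).
    """
    sub = table.entries[table.entries.output == output]
    if sub.empty:
        raise KeyError(f"output {output!r} not in table")
    sub = sub[~sub.species.isin(exclude)].copy()
    sub["absS"] = sub.S.abs()
    sub = sub.sort_values(["absS", "species"], ascending=[False, True])
    return sub.drop(columns="absS").reset_index(drop=True)
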
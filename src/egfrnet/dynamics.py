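"""Mass-action ODE assembly, stiff integration with timed events, and
trajectory readouts.

Each reaction contributes an elementary flux ``k * prod(reactant amounts)``
(reversible rows contribute a forward and a backward flux).  Species tagged
``clamped`` have zero derivative.  Integration uses scipy's LSODA with an
analytic Jacobian; events are applied as discontinuities with the
integration restarted, never left to step rejection.

Readout totals follow the moiety rule: ``p-ERK`` is the summed amount of
every species whose name contains the ``p-ERK`` token (free p-ERK plus all
its complexes), and likewise for ``p-AKT``, ``p-p38`` and ``Ras-GTP``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .builder import VariantSpec, apply_variant, receptor_active_species
from .network import Law, Model, expand_enzymatic, moiety_count, species_tokens

__all__ = [
    "Scenario",
    "Trajectory",
    "READOUTS",
    "SolverOptions",
    "assemble_rhs",
    "pre_equilibrate",
    "simulate",
    "peak_time",
    "time_to_basal",
    "fold_change",
    "readout_indices",
    "EquilibrationError",
    "IntegrationError",
]

#: readout name -> token that identifies the moiety in species names
READOUTS = {
    "p-ERK": "p-ERK",
    "p-AKT": "p-AKT",
    "p-p38": "p-p38",
    "Ras-GTP": "RasGTP",
}


class IntegrationError(RuntimeError):
    def __init__(self, message, time=None, state=None):
        self.time, self.state = time, state
        super().__init__(message)


class EquilibrationError(RuntimeError):
    def __init__(self, message, residual=None):
        self.residual = residual
        super().__init__(message)


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-9       # nM
    method: str = "LSODA"


@dataclass
class Scenario:
    """A simulation protocol.

    ``stimulus`` is ``(species, dose_nM, mode)`` with mode ``pulse`` (a bolus
    added at t = 0 and consumed naturally) or ``clamp`` (held constant).
    ``events`` are ``(time, VariantSpec)`` pairs applied as discontinuities.
    """

    t_end: float
    stimulus: tuple[str, float, str] | None = None
    variants: list[VariantSpec] = field(default_factory=list)
    sample_grid: np.ndarray | None = None
    events: list[tuple[float, VariantSpec]] = field(default_factory=list)
    solver: SolverOptions = SolverOptions()

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.sample_grid is None:
            self.sample_grid = np.linspace(0.0, self.t_end, 601)
        self.sample_grid = np.asarray(self.sample_grid, dtype=float)
        if self.sample_grid[0] < 0 or self.sample_grid[-1] > self.t_end + 1e-9:
            raise ValueError("sample_grid must lie within [0, t_end]")
        if np.any(np.diff(self.sample_grid) <= 0):
            raise ValueError("sample_grid must be strictly increasing")
        for t, _ in self.events:
            if not 0.0 < t < self.t_end:
                raise ValueError("event times must lie in (0, t_end)")
        if self.stimulus is not None and self.stimulus[2] not in ("pulse", "clamp"):
            raise ValueError(f"unknown stimulus mode {self.stimulus[2]!r}")


@dataclass
class Trajectory:
    """Time-indexed species amounts plus derived readout totals."""

    times: np.ndarray
    amounts: pd.DataFrame           # index: time, columns: species
    readouts: pd.DataFrame          # index: time, columns: READOUTS
    basal: dict[str, float]         # pre-stimulus basal readout values
    basal_state: np.ndarray
    model: Model

    def readout(self, name: str) -> np.ndarray:
        if name not in self.readouts.columns:
            raise KeyError(f"unknown readout {name!r}")
        return self.readouts[name].to_numpy()

    def series(self, name: str) -> np.ndarray:
        """A readout total if ``name`` is one, else the raw species series."""
        if name in self.readouts.columns:
            return self.readouts[name].to_numpy()
        if name in self.amounts.columns:
            return self.amounts[name].to_numpy()
        raise KeyError(f"{name!r} is neither a readout nor a species")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, quantity, value) table of the readouts."""
        df = self.readouts.reset_index().melt(id_vars="time", var_name="quantity",
                                              value_name="value")
        return df.sort_values(["quantity", "time"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# RHS assembly
# ---------------------------------------------------------------------------

def readout_indices(model: Model) -> dict[str, np.ndarray]:
    """Species indices contributing to each readout total."""
    out = {}
    for name, token in READOUTS.items():
        idx = [i for i, s in enumerate(model.species)
               if token in species_tokens(s.name)]
        out[name] = np.array(idx, dtype=int)
    return out


class MassActionRHS:
    """Derivative and Jacobian evaluator for a mass-action model."""

    def __init__(self, model: Model):
        if any(r.law is Law.ENZYMATIC_TWO_STEP for r in model.reactions):
            model = expand_enzymatic(model)
        self.model = model
        idx = model.species_index
        n = len(model.species)
        i1, i2, k, cols = [], [], [], []

        def add(reactants, products, value):
            r = [idx[s] for s in reactants]
            i1.append(r[0] if r else -1)
            i2.append(r[1] if len(r) > 1 else -1)
            k.append(value)
            col = np.zeros(n)
            for s in reactants:
                col[idx[s]] -= 1
            for s in products:
                col[idx[s]] += 1
            cols.append(col)

        for rxn in model.reactions:
            add(rxn.reactants, rxn.products, rxn.constants["kf"].value)
            if rxn.law is Law.MASS_ACTION_REVERSIBLE:
                add(rxn.products, rxn.reactants, rxn.constants["kr"].value)

        self.n = n
        self.k = np.array(k)
        self.i1 = np.array(i1, dtype=int)
        self.i2 = np.array(i2, dtype=int)
        self.N = np.array(cols).T          # (n_species, n_directions)
        self.clamped = np.array([i for i, s in enumerate(model.species)
                                 if "clamped" in s.role_tags], dtype=int)
        # zero-order directions (no reactants) are constant sources
        self._m1 = self.i1 >= 0
        self._m2 = self.i2 >= 0
        self._j1 = np.where(self.i1 >= 0, self.i1, 0)
        self._j2 = np.where(self.i2 >= 0, self.i2, 0)

    def rates(self, x: np.ndarray) -> np.ndarray:
        r = self.k.copy()
        r[self._m1] *= x[self._j1[self._m1]]
        r[self._m2] *= x[self._j2[self._m2]]
        return r

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.n:
            raise ValueError(f"state length {x.shape[-1]} != {self.n} species")
        dx = self.N @ self.rates(x)
        if self.clamped.size:
            dx[self.clamped] = 0.0
        return dx

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        nd = self.k.size
        D = np.zeros((nd, self.n))
        rows = np.arange(nd)
        # d rate / d x[i1] and / d x[i2]; the i1 == i2 (A + A) case lands twice
        m1, m2 = self._m1, self._m2
        contrib1 = np.where(m2, self.k * np.where(m2, x[self._j2], 1.0), self.k)
        np.add.at(D, (rows[m1], self.i1[m1]), contrib1[m1])
        contrib2 = self.k * x[self._j1]
        np.add.at(D, (rows[m2], self.i2[m2]), contrib2[m2])
        J = self.N @ D
        if self.clamped.size:
            J[self.clamped, :] = 0.0
        return J


def assemble_rhs(model: Model) -> MassActionRHS:
    """Build a ``(t, state) -> derivative`` evaluator for a valid model."""
    return MassActionRHS(model)


# ---------------------------------------------------------------------------
# pre-equilibration
# ---------------------------------------------------------------------------

def _stimulus_species(model: Model) -> list[str]:
    return [s.name for s in model.species
            if any(t.startswith("stimulus:") for t in s.role_tags)]


def pre_equilibrate(model: Model, horizon: float = 5000.0,
                    residual_tol: float = 1e-7,
                    solver: SolverOptions = SolverOptions(),
                    resting: float = 0.0) -> np.ndarray:
    """Relax the model to its pre-stimulus basal steady state.

    The stimulus species is held at ``resting`` (default 0 nM) during
    relaxation.  Returns the basal state vector; raises
    :class:`EquilibrationError` with the residual if ``max |dx/dt|`` does not
    fall below ``residual_tol`` (nM/min) within ``horizon`` minutes.
    """
    work = model
    stim = _stimulus_species(model)
    if stim:
        species = [replace(s, role_tags=s.role_tags | {"clamped"},
                           initial_amount=resting)
                   if s.name in stim else s for s in model.species]
        work = Model(species, list(model.reactions), dict(model.metadata))
    rhs = MassActionRHS(work)
    x = work.initial_state()
    t, chunk = 0.0, max(horizon / 4.0, 100.0)
    while t < horizon:
        sol = solve_ivp(rhs, (t, t + chunk), x, method=solver.method,
                        jac=rhs.jac, rtol=solver.rtol, atol=solver.atol)
        if not sol.success:
            raise EquilibrationError(f"equilibration failed: {sol.message}")
        x = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(rhs(t, x))) < residual_tol:
            break
    resid = float(np.max(np.abs(rhs(t, x))))
    if resid >= residual_tol:
        raise EquilibrationError(
            f"no steady state within {horizon} min (residual {resid:.3e} nM/min)",
            residual=resid)
    return np.clip(x, 0.0, None)


_BASAL_CACHE: dict = {}


def _basal_cached(model: Model, solver: SolverOptions) -> np.ndarray:
    key = (id(model), solver)
    fp = model.metadata.get("fingerprint")
    if fp is None:
        # structural fingerprint: species + reaction constants
        fp = hash((tuple((s.name, s.initial_amount, tuple(sorted(s.role_tags)))
                         for s in model.species),
                   tuple((r.id, tuple(sorted((p.name, p.value)
                                             for p in r.constants.values())))
                         for r in model.reactions)))
    key = (fp, solver)
    if key not in _BASAL_CACHE:
        _BASAL_CACHE[key] = pre_equilibrate(model, solver=solver)
    return _BASAL_CACHE[key]


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _apply_event(model: Model, state: np.ndarray, basal: np.ndarray,
                 spec: VariantSpec) -> tuple[Model, np.ndarray]:
    """Apply a timed intervention, returning the post-event model and state."""
    if spec.kind != "inhibit_EGFR_at_time":
        new_model = apply_variant(model, spec)
        # project the state onto the surviving species
        idx = model.species_index
        new_state = np.array([state[idx[s.name]] if s.name in idx else 0.0
                              for s in new_model.species])
        return new_model, new_state

    # EGFR inhibition: reset active receptor species to basal, return their
    # non-receptor constituents to the free pools, drop trans-phosphorylation
    # to a basal leak.
    leak = float(spec.parameters.get("leak_factor", 1e-4))
    idx = model.species_index
    state = state.copy()
    for name in receptor_active_species(model):
        i = idx[name]
        freed = max(state[i] - basal[i], 0.0)
        state[i] = basal[i]
        if freed <= 0:
            continue
        for tok in species_tokens(name):
            if tok in ("EGF", "EGFR", "p-EGFR"):
                continue       # ligand/receptor moiety is silenced, not freed
            if tok in idx:
                state[idx[tok]] += freed
    updates = {}
    for rxn in model.reactions:
        if "transphosphorylation" in rxn.tags:
            p = rxn.constants["kf"]
            updates[p.name] = p.value * leak
    new_model = model.with_parameters(updates) if updates else model
    return new_model, state


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _integrate(rhs: MassActionRHS, t0: float, t1: float, x0: np.ndarray,
               t_eval: np.ndarray, solver: SolverOptions):
    sol = solve_ivp(rhs, (t0, t1), x0, method=solver.method, jac=rhs.jac,
                    t_eval=t_eval if t_eval.size else None,
                    rtol=solver.rtol, atol=solver.atol)
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1] if sol.t.size else t0}: "
                               f"{sol.message}",
                               time=sol.t[-1] if sol.t.size else t0,
                               state=sol.y[:, -1] if sol.t.size else x0)
    return sol


def simulate(model: Model, scenario: Scenario,
             basal_state: np.ndarray | None = None) -> Trajectory:
    """Simulate a scenario from the pre-equilibrated basal state.

    Variants are applied first, the variant model is relaxed to its basal
    steady state (stimulus at rest), the stimulus is applied at t = 0, and
    timed events are handled as discontinuities with the integrator
    restarted.  Without a stimulus there is no pre-stimulus reference to
    equilibrate against, so the declared initial state is used as given.
    """
    work = model
    for variant in scenario.variants:
        work = apply_variant(work, variant)
    events = sorted([*scenario.events, *work.metadata.get("events", [])],
                    key=lambda e: e[0])

    if basal_state is None:
        if scenario.stimulus is None:
            basal_state = work.initial_state()
        else:
            basal_state = _basal_cached(work, scenario.solver)
    x = basal_state.copy()

    idx = work.species_index
    if scenario.stimulus is not None:
        name, dose, mode = scenario.stimulus
        if name not in idx:
            raise IntegrationError(f"stimulus species {name!r} not in model")
        x[idx[name]] = dose
        if mode == "clamp":
            species = [replace(s, role_tags=s.role_tags | {"clamped"},
                               initial_amount=dose) if s.name == name else s
                       for s in work.species]
            work = Model(species, list(work.reactions), dict(work.metadata))

    grid = scenario.sample_grid
    cur_model, cur_x, t0 = work, x, 0.0
    basal_for_events = basal_state
    times_out: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    species_names = work.species_names        # fixed layout unless an event prunes

    breakpoints = [t for t, _ in events] + [scenario.t_end]
    ev_specs = [s for _, s in events]
    for seg, t1 in enumerate(breakpoints):
        rhs = MassActionRHS(cur_model)
        mask = (grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)
        t_eval = np.unique(np.concatenate([[t0], grid[mask], [t1]]))
        sol = _integrate(rhs, t0, t1, cur_x, t_eval, scenario.solver)
        keep = np.isin(sol.t, grid[mask])
        # avoid duplicating the breakpoint sample in the next segment
        if times_out and sol.t[keep].size and times_out[-1].size \
                and sol.t[keep][0] == times_out[-1][-1]:
            keep[np.argmax(keep)] = False
        times_out.append(sol.t[keep])
        rows.append(_expand_states(sol.y[:, keep].T, cur_model, species_names))
        cur_x = sol.y[:, -1]
        t0 = t1
        if seg < len(ev_specs):
            cur_model, cur_x = _apply_event(cur_model, cur_x, basal_for_events,
                                            ev_specs[seg])

    times = np.concatenate(times_out)
    amounts = pd.DataFrame(np.vstack(rows), index=pd.Index(times, name="time"),
                           columns=species_names)
    if np.any(amounts.to_numpy() < -10 * scenario.solver.atol - 1e-12):
        worst = float(amounts.to_numpy().min())
        raise IntegrationError(f"negative amounts beyond tolerance ({worst:.3e} nM)")

    ridx = readout_indices(work)
    rd = {name: amounts.iloc[:, cols].sum(axis=1).to_numpy() if cols.size else
          np.zeros_like(times) for name, cols in ridx.items()}
    readouts = pd.DataFrame(rd, index=amounts.index)
    basal_readouts = {name: float(basal_state[cols].sum()) if cols.size else 0.0
                      for name, cols in readout_indices(work).items()}
    return Trajectory(times, amounts, readouts, basal_readouts, basal_state, work)


def _expand_states(block: np.ndarray, model: Model,
                   layout: list[str]) -> np.ndarray:
    """Map a segment's states onto the full species layout (events may prune
    species; pruned columns read zero)."""
    if model.species_names == layout:
        return block
    idx = model.species_index
    out = np.zeros((block.shape[0], len(layout)))
    for j, name in enumerate(layout):
        if name in idx:
            out[:, j] = block[:, idx[name]]
    return out


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def peak_time(trajectory: Trajectory, readout: str,
              t_min: float | None = None, t_max: float | None = None) -> float:
    """Earliest time at which the readout attains its maximum (ties resolve
    to the earliest grid point); optional window restriction."""
    t = trajectory.times
    y = trajectory.readout(readout)
    mask = np.ones_like(t, dtype=bool)
    if t_min is not None:
        mask &= t >= t_min
    if t_max is not None:
        mask &= t <= t_max
    t, y = t[mask], y[mask]
    return float(t[int(np.argmax(y))])


def time_to_basal(trajectory: Trajectory, readout: str,
                  tol_fraction: float = 0.05) -> float | None:
    """Earliest post-peak time at which the readout is back within
    ``tol_fraction`` of its excursion above basal.

    Returns None if the readout never returns; raises ValueError if it never
    deviated from basal in the first place.
    """
    t = trajectory.times
    y = trajectory.readout(readout)
    basal = trajectory.basal[readout]
    i_peak = int(np.argmax(np.abs(y - basal)))
    excursion = abs(y[i_peak] - basal)
    if excursion <= max(1e-9, 1e-6 * max(abs(basal), 1.0)):
        raise ValueError(f"readout {readout!r} never deviated from basal")
    post = np.abs(y[i_peak:] - basal) <= tol_fraction * excursion
    if not post.any():
        return None
    return float(t[i_peak + int(np.argmax(post))])


def fold_change(trajectory: Trajectory, readout: str, t: float) -> float:
    """Readout value at time t relative to its basal value."""
    basal = trajectory.basal[readout]
    if basal <= 0:
        raise ZeroDivisionError(f"basal {readout} is zero; fold change undefined")
    y = trajectory.readout(readout)
    value = float(np.interp(t, trajectory.times, y))
    return value / basal
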
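"""Synthetic inputs: noisy phospho-protein time courses with known ground
truth, analytic-oracle cascade models, and random mass-action networks.

The time-course generator emulates the sparse, positive, scale-proportional
measurements a phospho-blot time course provides: a handful of sample times
and multiplicative log-normal noise with a stated coefficient of variation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Scenario, simulate
from .network import Law, Model, ModelError, Param, Reaction, Species

__all__ = [
    "SyntheticDataset",
    "generate_timecourse_dataset",
    "generate_linear_cascade",
    "analytic_cascade_solution",
    "generate_random_massaction",
]


@dataclass
class SyntheticDataset:
    """Noisy sampled readout time courses plus the generating truth."""

    observations: pd.DataFrame          # columns: time, readout, value
    sample_times: np.ndarray
    noise_cv: float
    seed: int
    truth: dict = field(default_factory=dict)

    def to_csv(self) -> str:
        return self.observations.to_csv(index=False)

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=1, sort_keys=True)


def generate_timecourse_dataset(model: Model, scenario: Scenario,
                                sample_times, noise_cv: float, seed: int,
                                readouts: list[str] | None = None,
                                ) -> SyntheticDataset:
    """Simulate, sample at ``sample_times`` and apply multiplicative
    log-normal noise with unit mean and the given CV.

    With ``noise_cv = 0`` the observations equal the simulated readouts
    exactly; identical arguments (including seed) regenerate the dataset
    bit-identically.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    sample_times = np.asarray(sample_times, dtype=float)
    traj = simulate(model, scenario)
    names = readouts or [c for c in traj.readouts.columns
                         if traj.readouts[c].abs().max() > 0]
    if not names:        # toy models without phospho-readouts: raw species
        names = [c for c in traj.amounts.columns
                 if traj.amounts[c].abs().max() > 0]
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(noise_cv ** 2)
    rows = []
    for name in names:
        clean = np.interp(sample_times, traj.times, traj.series(name))
        if noise_cv > 0:
            noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2),
                                  size=sample_times.size)
        else:
            noise = np.ones_like(sample_times)
        for t, v in zip(sample_times, clean * noise):
            rows.append({"time": t, "readout": name, "value": v})
    obs = pd.DataFrame(rows, columns=["time", "readout", "value"])
    truth = {
        "parameters": model.parameters,
        "initial_amounts": {s.name: s.initial_amount for s in model.species
                            if s.initial_amount > 0},
        "noise_cv": noise_cv,
        "seed": int(seed),
        "t_end": scenario.t_end,
        "sample_times": sample_times.tolist(),
    }
    return SyntheticDataset(obs, sample_times, noise_cv, int(seed), truth)


# ---------------------------------------------------------------------------
# sequential first-order cascade (analytic oracle)
# ---------------------------------------------------------------------------

def generate_linear_cascade(n: int, rates, x0: float = 1.0) -> Model:
    """Irreversible unary chain X1 -> X2 -> ... -> Xn with first-order rates.

    ``rates`` must hold n - 1 distinct positive values (the closed-form
    solution assumes distinct rates).  Only X1 starts nonzero (``x0`` nM).
    """
    rates = list(map(float, rates))
    if n < 2:
        raise ModelError("cascade needs at least two species")
    if len(rates) != n - 1:
        raise ModelError(f"need {n - 1} rates for {n} species")
    if len(set(rates)) != len(rates):
        raise ModelError("rates must be distinct (closed form assumes it)")
    if any(k <= 0 for k in rates):
        raise ModelError("rates must be positive")
    species = [Species(f"X{i + 1}", initial_amount=x0 if i == 0 else 0.0)
               for i in range(n)]
    reactions = [Reaction(f"c{i + 1}", (f"X{i + 1}",), (f"X{i + 2}",),
                          Law.MASS_ACTION_IRREVERSIBLE,
                          {"kf": Param(f"k{i + 1}", rates[i])})
                 for i in range(n - 1)]
    return Model(species, reactions, {"name": f"cascade{n}"})


def analytic_cascade_solution(rates, x0: float, t) -> np.ndarray:
    """Exact solution of the sequential first-order chain (Bateman form).

    Returns an array of shape (len(t), n_species) for the chain generated by
    :func:`generate_linear_cascade` with the same ``rates`` and ``x0``.
    """
    rates = np.asarray(rates, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = rates.size + 1
    lam = np.concatenate([rates, [0.0]])        # decay constant per species
    out = np.zeros((t.size, n))
    for i in range(n):
        lam_i = lam[: i + 1]
        prod_k = np.prod(rates[:i]) if i else 1.0
        acc = np.zeros_like(t)
        for j in range(i + 1):
            denom = np.prod([lam_i[l] - lam_i[j] for l in range(i + 1) if l != j])
            acc += np.exp(-lam_i[j] * t) / (denom if i else 1.0)
        out[:, i] = x0 * prod_k * acc
    return out


# ---------------------------------------------------------------------------
# random mass-action networks (property-test factory)
# ---------------------------------------------------------------------------

def generate_random_massaction(n_species: int, n_reactions: int, seed: int,
                               conversion_only: bool = False) -> Model:
    """Seeded random valid model with molecularity <= 2 on both sides.

    A spanning chain of conversions guarantees no orphan species; remaining
    reactions are drawn among conversions, bindings (A + B -> C) and
    dissociations (C -> A + B), optionally reversible.  With
    ``conversion_only`` every reaction is a unary conversion, so total mass
    is conserved.
    """
    if n_species < 2:
        raise ModelError("need at least two species")
    if n_reactions < n_species - 1:
        raise ModelError("need at least n_species - 1 reactions (spanning chain)")
    rng = np.random.default_rng(seed)
    names = [f"S{i}" for i in range(n_species)]
    species = [Species(n, initial_amount=float(np.round(rng.uniform(0.5, 10.0), 3))
                       if rng.random() < 0.7 else 0.0) for n in names]
    reactions: list[Reaction] = []

    def kval() -> float:
        return float(np.round(10.0 ** rng.uniform(-2, 0.5), 6))

    for i in range(n_species - 1):
        reactions.append(Reaction(
            f"r{len(reactions):03d}", (names[i],), (names[i + 1],),
            Law.MASS_ACTION_IRREVERSIBLE,
            {"kf": Param(f"p{len(reactions):03d}", kval())}))
    while len(reactions) < n_reactions:
        rid = f"r{len(reactions):03d}"
        pname = f"p{len(reactions):03d}"
        if conversion_only:
            a, c = rng.choice(n_species, size=2, replace=False)
            reactions.append(Reaction(rid, (names[a],), (names[c],),
                                      Law.MASS_ACTION_IRREVERSIBLE,
                                      {"kf": Param(pname, kval())}))
            continue
        kind = rng.integers(0, 3)
        reversible = rng.random() < 0.4
        if kind == 0:      # conversion
            a, c = rng.choice(n_species, size=2, replace=False)
            reactants, products = (names[a],), (names[c],)
        elif kind == 1:    # binding
            a, bq = rng.choice(n_species, size=2, replace=False)
            c = int(rng.integers(0, n_species))
            reactants, products = (names[a], names[bq]), (names[c],)
        else:              # dissociation
            a = int(rng.integers(0, n_species))
            c, d = rng.choice(n_species, size=2, replace=False)
            reactants, products = (names[a],), (names[c], names[d])
        consts = {"kf": Param(pname, kval())}
        law = Law.MASS_ACTION_IRREVERSIBLE
        if reversible:
            consts["kr"] = Param(pname + "r", kval())
            law = Law.MASS_ACTION_REVERSIBLE
        reactions.append(Reaction(rid, reactants, products, law, consts))
    return Model(species, reactions, {"name": f"random-{seed}"})
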
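"""Canned computational experiments reproducing the model's analyses
end-to-end, with manifests for reproducibility.

Six experiments mirror the model's published use: transient-stimulation
validation, sustained receptor activation, acute receptor inactivation,
the two structural knockouts (AKT->ASK1 crosstalk, ROS), and the
normalized time-integrated sensitivity scan.  Each writes tidy CSV output
plus a JSON summary, and returns a :class:`RunManifest` listing every file
with its checksum alongside the solver settings and seeds used.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import VariantSpec, build_egfr_network
from .dynamics import (
    Scenario,
    SolverOptions,
    peak_time,
    simulate,
    time_to_basal,
)
from .network import Model, write_reaction_table
from .sensitivity import rank_sensitivities, sensitivity_scan

__all__ = ["RunManifest", "run_experiment", "run_all", "EXPERIMENTS",
           "REFERENCE_DOSE_NM", "transient_scenario", "sustained_scenario",
           "acute_inactivation_scenario", "load_scenario_definitions"]


def load_scenario_definitions() -> dict:
    """The canonical scenario definitions shipped with the package
    (``data/scenarios.yaml``): stimulus, horizon, variants and events for
    each named protocol."""
    import importlib.resources as resources

    import yaml

    text = (resources.files("egfrnet") / "data" / "scenarios.yaml").read_text()
    return yaml.safe_load(text)

#: reference EGF dose (nM); stimulus doses are multiples of this
REFERENCE_DOSE_NM = 100.0
#: minutes of sustained activation before the inhibition event
_PRE_EVENT_MIN = 360.0
#: post-inhibition horizon (24 h)
_POST_EVENT_MIN = 1440.0

_SUSTAINED_VARIANTS = (VariantSpec("remove_internalization"),
                       VariantSpec("clamp_EGF"))


def transient_scenario(dose: float = REFERENCE_DOSE_NM, t_end: float = 60.0,
                       n_points: int = 601) -> Scenario:
    """One-time EGF bolus at t = 0, consumed naturally."""
    return Scenario(t_end=t_end, stimulus=("EGF", dose, "pulse"),
                    sample_grid=np.linspace(0.0, t_end, n_points))


def sustained_scenario(dose: float = REFERENCE_DOSE_NM, t_end: float = 120.0,
                       extra_variants: tuple[VariantSpec, ...] = (),
                       n_points: int = 601) -> Scenario:
    """EGF clamped, internalization removed (the receptor-addicted state)."""
    return Scenario(t_end=t_end, stimulus=("EGF", dose, "clamp"),
                    variants=[*_SUSTAINED_VARIANTS, *extra_variants],
                    sample_grid=np.linspace(0.0, t_end, n_points))


def acute_inactivation_scenario(dose: float = REFERENCE_DOSE_NM,
                                extra_variants: tuple[VariantSpec, ...] = (),
                                post_horizon: float = _POST_EVENT_MIN,
                                ) -> Scenario:
    """Sustained activation run to steady state, then the receptor is
    inhibited (reset to basal activity) and the network relaxes.

    The event occurs at t = ``_PRE_EVENT_MIN``; reported times are usually
    shifted so that the inhibition defines time zero.
    """
    t_end = _PRE_EVENT_MIN + post_horizon
    grid = np.unique(np.concatenate([
        np.linspace(0.0, _PRE_EVENT_MIN, 181),
        _PRE_EVENT_MIN + np.linspace(0.0, post_horizon, 721),
    ]))
    return Scenario(
        t_end=t_end, stimulus=("EGF", dose, "clamp"),
        variants=[*_SUSTAINED_VARIANTS, *extra_variants],
        events=[(_PRE_EVENT_MIN,
                 VariantSpec("inhibit_EGFR_at_time", {"time": _PRE_EVENT_MIN}))],
        sample_grid=grid)


# ---------------------------------------------------------------------------
# manifest plumbing
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Record of one (or several) experiment runs."""

    config: dict
    model_checksums: dict[str, str]
    solver: dict
    seed: int | None = None
    experiments: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "model_checksums": self.model_checksums,
            "solver": self.solver,
            "seed": self.seed,
            "experiments": self.experiments,
        }, indent=1, sort_keys=True)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _model_checksums(model: Model) -> dict[str, str]:
    rtab, itab = write_reaction_table(model)
    return {"reactions.tsv": _sha256(rtab), "initials.tsv": _sha256(itab)}


def _write(out_dir: Path, name: str, text: str, inventory: list[dict]):
    path = out_dir / name
    path.write_text(text)
    inventory.append({"file": name, "sha256": _sha256(text)})


# ---------------------------------------------------------------------------
# experiment implementations
# ---------------------------------------------------------------------------

def _traj_csv(traj) -> str:
    return traj.to_tidy().to_csv(index=False)


def _summarize_timings(traj) -> dict:
    out = {}
    for r in ("p-ERK", "p-AKT", "p-p38", "Ras-GTP"):
        out[f"{r}.peak_time_min"] = peak_time(traj, r)
        out[f"{r}.peak_nM"] = float(np.max(traj.readout(r)))
        out[f"{r}.basal_nM"] = traj.basal[r]
    try:
        out["p-ERK.time_to_basal_min"] = time_to_basal(traj, "p-ERK", 0.05)
    except ValueError:
        out["p-ERK.time_to_basal_min"] = None
    return out


def _exp_validation_transient(model, config, out_dir, inventory):
    sc = transient_scenario(dose=config.get("dose_nM", REFERENCE_DOSE_NM))
    traj = simulate(model, sc)
    _write(out_dir, "validation_transient.csv", _traj_csv(traj), inventory)
    summary = _summarize_timings(traj)
    summary["p-p38_peak_after_p-ERK"] = bool(
        peak_time(traj, "p-p38") > peak_time(traj, "p-ERK"))
    return summary


def _plateau(traj, readout, window=20.0) -> float:
    mask = traj.times >= traj.times[-1] - window
    return float(np.mean(traj.readout(readout)[mask]))


def _exp_sustained(model, config, out_dir, inventory,
                   extra_variants=(), stem="sustained"):
    sc = sustained_scenario(dose=config.get("dose_nM", REFERENCE_DOSE_NM),
                            extra_variants=extra_variants)
    traj = simulate(model, sc)
    _write(out_dir, f"{stem}.csv", _traj_csv(traj), inventory)
    summary = {}
    for r in ("p-ERK", "p-AKT", "p-p38"):
        summary[f"{r}.plateau_nM"] = _plateau(traj, r)
        summary[f"{r}.basal_nM"] = traj.basal[r]
    summary["p-p38.early_peak_time_min"] = peak_time(traj, "p-p38", t_max=30.0)
    summary["p-p38.early_peak_nM"] = float(
        np.max(traj.readout("p-p38")[traj.times <= 30.0]))
    return summary


def _exp_acute(model, config, out_dir, inventory, extra_variants=(),
               stem="acute_inactivation"):
    sc = acute_inactivation_scenario(
        dose=config.get("dose_nM", REFERENCE_DOSE_NM),
        extra_variants=extra_variants)
    traj = simulate(model, sc)
    df = traj.to_tidy()
    df["time"] = df["time"] - _PRE_EVENT_MIN       # inhibition defines t = 0
    _write(out_dir, f"{stem}.csv", df.to_csv(index=False), inventory)
    t = traj.times
    summary = {}
    for r in ("p-ERK", "p-AKT", "p-p38"):
        y = traj.readout(r)
        pre = float(np.interp(_PRE_EVENT_MIN, t, y))
        post = t > _PRE_EVENT_MIN
        summary[f"{r}.pre_event_nM"] = pre
        summary[f"{r}.post_max_nM"] = float(np.max(y[post]))
        summary[f"{r}.post_peak_time_min"] = float(
            t[post][np.argmax(y[post])] - _PRE_EVENT_MIN)
        summary[f"{r}.at_1h_nM"] = float(np.interp(_PRE_EVENT_MIN + 60.0, t, y))
    return summary


def _exp_variant(model, config, out_dir, inventory, kind, stem):
    extra = (VariantSpec(kind),)
    s1 = _exp_sustained(model, config, out_dir, inventory,
                        extra_variants=extra, stem=f"{stem}_sustained")
    s2 = _exp_acute(model, config, out_dir, inventory,
                    extra_variants=extra, stem=f"{stem}_inhibited")
    return {"sustained": s1, "inhibited": s2}


def _exp_sensitivity(model, config, out_dir, inventory):
    sc = transient_scenario(dose=config.get("dose_nM", REFERENCE_DOSE_NM),
                            n_points=301)
    table = sensitivity_scan(model, sc,
                             delta_fraction=config.get("delta_fraction", 0.1))
    _write(out_dir, "sensitivity.csv", table.to_frame().to_csv(index=False),
           inventory)
    summary = {"delta_fraction": table.delta_fraction,
               "window_min": list(table.window), "top": {}}
    trivial = {"p-ERK": ("ERK", "EGF"), "p-AKT": ("AKT", "EGF"),
               "p-p38": ("p38", "EGF")}
    for out, excl in trivial.items():
        ranked = rank_sensitivities(table, out, exclude=excl)
        summary["top"][out] = ranked.head(8)[["species", "S"]].to_dict("records")
    return summary


EXPERIMENTS = {
    "validation_transient": _exp_validation_transient,
    "sustained": _exp_sustained,
    "acute_inactivation": _exp_acute,
    "variant_crosstalk": lambda m, c, d, inv: _exp_variant(
        m, c, d, inv, "remove_crosstalk_AKT_ASK1", "crosstalk_removed"),
    "variant_ros": lambda m, c, d, inv: _exp_variant(
        m, c, d, inv, "remove_ROS", "ros_removed"),
    "sensitivity_scan": _exp_sensitivity,
}


def run_experiment(name: str, config: dict | None = None,
                   out_dir: str | Path = "results", seed: int | None = None,
                   model: Model | None = None) -> RunManifest:
    """Run one named experiment; writes CSV/JSON outputs and a manifest."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"choose from {sorted(EXPERIMENTS)}")
    config = dict(config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model if model is not None else build_egfr_network()
    inventory: list[dict] = []
    t0 = _time.perf_counter()
    summary = EXPERIMENTS[name](model, config, out_dir, inventory)
    elapsed = _time.perf_counter() - t0
    summary_text = json.dumps(summary, indent=1, sort_keys=True)
    _write(out_dir, f"{name}_summary.json", summary_text, inventory)
    manifest = RunManifest(
        config={"experiment": name, **config},
        model_checksums=_model_checksums(model),
        solver={"rtol": SolverOptions().rtol, "atol": SolverOptions().atol,
                "method": SolverOptions().method},
        seed=seed,
        experiments=[{"name": name, "elapsed_s": round(elapsed, 3),
                      "outputs": inventory, "status": "ok"}])
    (out_dir / f"{name}_manifest.json").write_text(manifest.to_json())
    return manifest


def run_all(config: dict | None = None, out_dir: str | Path = "results",
            seed: int | None = None) -> RunManifest:
    """Run every experiment; one combined manifest.

    A failing experiment is recorded with its error and does not abort the
    rest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = build_egfr_network()
    combined = RunManifest(
        config=dict(config or {}), model_checksums=_model_checksums(model),
        solver={"rtol": SolverOptions().rtol, "atol": SolverOptions().atol,
                "method": SolverOptions().method},
        seed=seed)
    for name in EXPERIMENTS:
        try:
            m = run_experiment(name, config, out_dir, seed=seed, model=model)
            combined.experiments.extend(m.experiments)
        except Exception as exc:   # record, continue
            combined.experiments.append(
                {"name": name, "status": "failed", "error": str(exc)})
    (out_dir / "manifest.json").write_text(combined.to_json())
    return combined
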
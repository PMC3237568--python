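"""Kinetic parameter estimation by multi-start bounded least squares.

A :class:`TimecourseFit` couples a model, a simulation scenario and a tidy
observation table (time, readout, value); ``fit()`` runs a seeded multi-start
ensemble of trust-region least-squares solves in log-parameter space and
returns a :class:`FitResult` carrying the best estimate, the full ensemble,
approximate standard errors and a ``summary()`` table.

Fitting in log space enforces positivity and copes with the decade-scale
spread of kinetic constants.  The ensemble is a deliberately simple
multi-start scheme; it is not a posterior and the standard errors are the
usual local Gauss-Newton approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import Scenario, simulate
from .network import Model

__all__ = ["TimecourseFit", "FitProblem", "FitResult"]

_PENALTY = 1e3   # residual magnitude substituted when a simulation fails


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of a multi-start fit."""

    params: dict[str, float]            # best estimate
    loss: float
    ensemble: pd.DataFrame              # one row per start: params, loss, status
    bse: dict[str, float]               # Gauss-Newton standard errors
    seed: int
    n_starts: int
    nfev: int = 0

    @property
    def best_estimate(self) -> dict[str, float]:
        return self.params

    def summary(self) -> str:
        lines = [
            "Time-course least-squares fit",
            "=" * 46,
            f"starts: {self.n_starts}    seed: {self.seed}    "
            f"best loss: {self.loss:.6g}",
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}",
            "-" * 46,
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<20}{value:>12.5g}{se:>12.3g}")
        return "\n".join(lines)


class TimecourseFit:
    """Least-squares calibration of selected rate constants.

    Parameters
    ----------
    model
        The model whose named rate constants are to be adjusted.
    scenario
        Simulation protocol reproducing the experiment that generated the
        data.
    data
        Tidy table with columns ``time``, ``readout``, ``value``.
    free_parameters
        Mapping parameter name -> (lower, upper) positive bounds.
    weights
        Optional per-readout weights (default 1).
    """

    def __init__(self, model: Model, scenario: Scenario, data: pd.DataFrame,
                 free_parameters: dict[str, tuple[float, float]],
                 weights: dict[str, float] | None = None):
        for col in ("time", "readout", "value"):
            if col not in data.columns:
                raise ValueError(f"data missing column {col!r}")
        known = model.parameters
        for name, (lo, hi) in free_parameters.items():
            if name not in known:
                raise ValueError(f"unknown parameter {name!r}")
            if not (0 < lo < hi) or not np.isfinite(hi):
                raise ValueError(f"bounds for {name!r} must be finite with 0 < lo < hi")
        self.model = model
        self.scenario = scenario
        self.data = data.reset_index(drop=True)
        self.free = dict(free_parameters)
        self.weights = dict(weights or {})
        self._names = list(self.free)

    @classmethod
    def from_dataframe(cls, model: Model, scenario: Scenario, data: pd.DataFrame,
                       free_parameters: dict[str, tuple[float, float]],
                       **kw) -> "TimecourseFit":
        return cls(model, scenario, data, free_parameters, **kw)

    # -- objective --------------------------------------------------------
    def _residuals(self, values: np.ndarray) -> np.ndarray:
        params = dict(zip(self._names, values))
        try:
            traj = simulate(self.model.with_parameters(params), self.scenario)
        except Exception:
            return np.full(len(self.data), _PENALTY)
        out = np.empty(len(self.data))
        for i, row in self.data.iterrows():
            w = self.weights.get(row["readout"], 1.0)
            sim = np.interp(row["time"], traj.times, traj.series(row["readout"]))
            out[i] = w * (sim - row["value"])
        return out

    def loss(self, params: dict[str, float] | np.ndarray) -> float:
        """Weighted sum of squared residuals at the given parameter values."""
        if isinstance(params, dict):
            values = np.array([params[n] for n in self._names])
        else:
            values = np.asarray(params, dtype=float)
        r = self._residuals(values)
        return float(np.sum(r ** 2))

    # -- fitting ----------------------------------------------------------
    def fit(self, n_starts: int = 10, seed: int = 0) -> FitResult:
        """Multi-start bounded least squares; deterministic given the seed.

        Start 1 is the model's current parameter values (clipped into
        bounds); the rest are drawn log-uniformly within bounds.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self._names:
            baseline = self.loss(np.array([]))
            ens = pd.DataFrame([{"start": 0, "loss": baseline, "status": 0}])
            return FitResult(params={}, loss=baseline, ensemble=ens, bse={},
                             seed=seed, n_starts=n_starts)
        rng = np.random.default_rng(seed)
        lo = np.log(np.array([self.free[n][0] for n in self._names]))
        hi = np.log(np.array([self.free[n][1] for n in self._names]))
        current = np.log(np.clip(
            [self.model.parameters[n] for n in self._names],
            np.exp(lo), np.exp(hi)))
        starts = [current]
        for _ in range(n_starts - 1):
            starts.append(lo + rng.random(len(self._names)) * (hi - lo))

        def f(logx):
            return self._residuals(np.exp(logx))

        rows, sols, nfev = [], [], 0
        for i, x0 in enumerate(starts):
            sol = least_squares(f, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-12, gtol=1e-10)
            nfev += sol.nfev
            rows.append({"start": i, "loss": float(sol.cost * 2),
                         "status": int(sol.status),
                         **{n: float(v) for n, v in
                            zip(self._names, np.exp(sol.x))}})
            sols.append(sol)
        ensemble = pd.DataFrame(rows)
        best_i = int(ensemble.loss.idxmin())
        best = sols[best_i]
        est = np.exp(best.x)

        # Gauss-Newton covariance in log space, mapped back by the delta rule
        bse = {}
        try:
            m, n = best.jac.shape
            if m > n:
                jtj = best.jac.T @ best.jac
                s2 = 2 * best.cost / max(m - n, 1)
                cov_log = s2 * np.linalg.pinv(jtj)
                for j, name in enumerate(self._names):
                    bse[name] = float(np.sqrt(max(cov_log[j, j], 0.0)) * est[j])
        except Exception:
            pass
        return FitResult(
            params={n: float(v) for n, v in zip(self._names, est)},
            loss=float(best.cost * 2), ensemble=ensemble, bse=bse,
            seed=seed, n_starts=n_starts, nfev=nfev)


# Backwards-compatible alias: the problem definition and the fitter are the
# same object in this package.
FitProblem = TimecourseFit
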
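"""ODE assembly, integration, events and trajectory statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from egfrnet.builder import VariantSpec
from egfrnet.dynamics import (
    Scenario,
    SolverOptions,
    Trajectory,
    assemble_rhs,
    fold_change,
    peak_time,
    pre_equilibrate,
    simulate,
    time_to_basal,
)
from egfrnet.experiments import sustained_scenario, transient_scenario
from egfrnet.network import (
    Law,
    Model,
    Param,
    Reaction,
    Species,
    conserved_moieties,
    conservation_values,
    moiety_count,
)
from egfrnet.synthetic import (
    analytic_cascade_solution,
    generate_linear_cascade,
    generate_random_massaction,
)


def _toy(reactions, species):
    return Model([Species(n, initial_amount=a) for n, a in species], reactions)


class TestAssembleRHS:
    def test_unimolecular_closed_form(self):
        m = _toy([Reaction("r", ("A",), ("B",), Law.MASS_ACTION_IRREVERSIBLE,
                           {"kf": Param("k", 1.0)})], [("A", 2.0), ("B", 0.0)])
        rhs = assemble_rhs(m)
        dx = rhs(0.0, np.array([2.0, 0.0]))
        assert dx == pytest.approx([-2.0, 2.0])

    def test_bimolecular_closed_form(self):
        m = _toy([Reaction("r", ("A", "B"), ("C",), Law.MASS_ACTION_IRREVERSIBLE,
                           {"kf": Param("k", 0.5)})],
                 [("A", 2.0), ("B", 3.0), ("C", 0.0)])
        rhs = assemble_rhs(m)
        dx = rhs(0.0, np.array([2.0, 3.0, 0.0]))
        assert dx[2] == pytest.approx(3.0)

    def test_dimerization_counts_twice(self):
        m = _toy([Reaction("r", ("A", "A"), ("D",), Law.MASS_ACTION_IRREVERSIBLE,
                           {"kf": Param("k", 1.0)})], [("A", 3.0), ("D", 0.0)])
        rhs = assemble_rhs(m)
        dx = rhs(0.0, np.array([3.0, 0.0]))
        assert dx == pytest.approx([-18.0, 9.0])

    def test_state_length_mismatch_raises(self):
        m = generate_random_massaction(4, 5, seed=0)
        with pytest.raises(ValueError):
            assemble_rhs(m)(0.0, np.zeros(3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_laws_annihilate_derivative(self, seed, rng):
        m = generate_random_massaction(6, 9, seed)
        rhs = assemble_rhs(m)
        laws = conserved_moieties(m)
        idx = m.species_index
        for _ in range(5):
            x = rng.uniform(0, 10, len(m.species))
            dx = rhs(0.0, x)
            for law in laws:
                v = np.zeros(len(m.species))
                for name, c in law.coefficients.items():
                    v[idx[name]] = c
                assert abs(v @ dx) < 1e-9

    @pytest.mark.parametrize("seed", [0, 5])
    def test_jacobian_matches_finite_differences(self, seed, rng):
        m = generate_random_massaction(5, 8, seed)
        rhs = assemble_rhs(m)
        x = rng.uniform(0.5, 5.0, len(m.species))
        J = rhs.jac(0.0, x)
        eps = 1e-6
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            col = (rhs(0.0, xp) - rhs(0.0, xm)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-6)


class TestPreEquilibrate:
    def test_fixed_point_is_returned_unchanged(self):
        m = _toy([Reaction("r", ("A",), ("B",), Law.MASS_ACTION_REVERSIBLE,
                           {"kf": Param("kf", 1.0), "kr": Param("kr", 1.0)})],
                 [("A", 1.0), ("B", 1.0)])
        x = pre_equilibrate(m, horizon=100.0)
        assert x == pytest.approx([1.0, 1.0], abs=1e-6)

    def test_detailed_balance_two_state(self):
        m = _toy([Reaction("r", ("A",), ("B",), Law.MASS_ACTION_REVERSIBLE,
                           {"kf": Param("kf", 1.0), "kr": Param("kr", 1.0)})],
                 [("A", 2.0), ("B", 0.0)])
        x = pre_equilibrate(m, horizon=200.0)
        assert x == pytest.approx([1.0, 1.0], abs=1e-6)

    def test_egfr_basal_residual_small(self, egfr_model):
        x = pre_equilibrate(egfr_model)
        rhs = assemble_rhs(egfr_model)
        # solver-independent residual check
        assert np.max(np.abs(rhs(0.0, x))) < 1e-7


class TestSimulate:
    def test_zero_stimulus_constant_at_basal(self, egfr_model):
        sc = Scenario(t_end=60.0, stimulus=("EGF", 0.0, "pulse"),
                      sample_grid=np.linspace(0, 60, 61))
        traj = simulate(egfr_model, sc)
        for r in ("p-ERK", "p-AKT", "p-p38"):
            y = traj.readout(r)
            assert np.allclose(y, traj.basal[r], rtol=1e-3, atol=1e-6)

    def test_linear_cascade_matches_bateman_solution(self):
        rates = [0.9, 0.4, 0.15]
        m = generate_linear_cascade(4, rates, x0=2.0)
        sc = Scenario(t_end=20.0, sample_grid=np.linspace(0, 20, 201),
                      solver=SolverOptions(rtol=1e-10, atol=1e-12))
        traj = simulate(m, sc)
        exact = analytic_cascade_solution(rates, 2.0, traj.times)
        assert np.allclose(traj.amounts.to_numpy(), exact, rtol=1e-6, atol=1e-9)

    def test_tolerance_tightening_changes_readouts_little(self, egfr_model):
        base = simulate(egfr_model, transient_scenario())
        tight = simulate(egfr_model, Scenario(
            t_end=60.0, stimulus=("EGF", 100.0, "pulse"),
            sample_grid=np.linspace(0, 60, 601),
            solver=SolverOptions(rtol=1e-7, atol=1e-10)))
        for r in ("p-ERK", "p-AKT", "p-p38"):
            a, b = base.readout(r), tight.readout(r)
            scale = np.max(np.abs(b))
            assert np.max(np.abs(a - b)) / scale < 1e-3

    def test_amounts_never_meaningfully_negative(self, transient_traj):
        assert transient_traj.amounts.to_numpy().min() >= -1e-8

    def test_conserved_moieties_constant_over_24h(self, egfr_model):
        """Kinase moieties (ERK, MEK, p38, AKT, Ras pools) drift < 1e-6
        relative over a simulated day of sustained signalling."""
        sc = sustained_scenario(t_end=1440.0, n_points=289)
        traj = simulate(egfr_model, sc)
        model = traj.model
        for token in ("ERK", "MEK", "p38", "AKT", "MKK", "PDK1", "PTEN"):
            cols = [i for i, s in enumerate(model.species)
                    if moiety_count(s.name, token) > 0]
            weights = np.array([moiety_count(model.species[i].name, token)
                                for i in cols], dtype=float)
            series = traj.amounts.iloc[:, cols].to_numpy() @ weights
            assert np.ptp(series) / series[0] < 1e-6, token

    def test_dose_response_is_monotone_nondecreasing(self, egfr_model):
        peaks = []
        for dose in (25.0, 50.0, 100.0, 200.0):
            traj = simulate(egfr_model, transient_scenario(dose=dose,
                                                           n_points=301))
            peaks.append(float(np.max(traj.readout("p-ERK"))))
        assert all(b >= a * (1 - 1e-9) for a, b in zip(peaks, peaks[1:]))


@pytest.fixture(scope="module")
def acute(egfr_model):
    from egfrnet.experiments import acute_inactivation_scenario
    return simulate(egfr_model, acute_inactivation_scenario())


class TestAcuteInactivation:

    def test_survival_signals_fall_immediately(self, acute):
        t = acute.times
        for r in ("p-ERK", "p-AKT"):
            seg = acute.readout(r)[(t > 360.0) & (t <= 380.0)]
            assert np.all(np.diff(seg) < 0), r

    def test_p38_rises_after_delay_above_pre_event(self, acute):
        t = acute.times
        y = acute.readout("p-p38")
        pre = float(np.interp(360.0, t, y))
        post = y[t > 360.0]
        t_post = t[t > 360.0] - 360.0
        assert post.max() > 5 * pre
        assert t_post[int(np.argmax(post))] > 5.0      # delayed, not instant

    def test_trajectory_grid_is_the_requested_grid(self, acute):
        from egfrnet.experiments import acute_inactivation_scenario
        grid = acute_inactivation_scenario().sample_grid
        assert np.array_equal(acute.times, grid)


class TestStatistics:
    def _traj(self, times, values, basal=0.0):
        df = pd.DataFrame({"x": values}, index=pd.Index(times, name="time"))
        return Trajectory(np.asarray(times, float), df, df.rename(columns={"x": "r"}),
                          {"r": basal}, np.zeros(1), Model())

    def test_peak_time_tie_breaks_to_earliest(self):
        tr = self._traj([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        assert peak_time(tr, "r") == 0.0

    def test_peak_time_monotone_series(self):
        tr = self._traj([0, 1, 2, 3], [0.0, 1.0, 2.0, 3.0])
        assert peak_time(tr, "r") == 3.0

    def test_peak_time_window_restriction(self):
        tr = self._traj([0, 1, 2, 3], [0.0, 5.0, 1.0, 9.0])
        assert peak_time(tr, "r") == 3.0
        assert peak_time(tr, "r", t_max=2.0) == 1.0

    def test_time_to_basal_exponential_closed_form(self):
        # decay to basal at rate 0.1/min from excursion 1: 5% at ln(20)/0.1
        t = np.linspace(0, 60, 6001)
        tr = self._traj(t, 2.0 + np.exp(-0.1 * t), basal=2.0)
        expected = math.log(20.0) / 0.1
        assert time_to_basal(tr, "r", 0.05) == pytest.approx(expected, abs=0.02)

    def test_time_to_basal_not_reached_is_none(self):
        t = np.linspace(0, 10, 101)
        tr = self._traj(t, 1.0 + t, basal=1.0)
        assert time_to_basal(tr, "r", 0.05) is None

    def test_time_to_basal_flat_series_raises(self):
        tr = self._traj([0, 1, 2], [1.0, 1.0, 1.0], basal=1.0)
        with pytest.raises(ValueError):
            time_to_basal(tr, "r", 0.05)

    def test_fold_change_constant_and_doubled(self):
        tr = self._traj([0, 1, 2], [2.0, 2.0, 4.0], basal=2.0)
        assert fold_change(tr, "r", 0.5) == pytest.approx(1.0)
        assert fold_change(tr, "r", 2.0) == pytest.approx(2.0)

    def test_fold_change_zero_basal_raises(self):
        tr = self._traj([0, 1], [1.0, 1.0], basal=0.0)
        with pytest.raises(ZeroDivisionError):
            fold_change(tr, "r", 0.5)

    def test_fixture_sustained_fold_change_above_one(self, sustained_traj):
        assert fold_change(sustained_traj, "p-ERK", 120.0) > 1.0


class TestScenarioValidation:
    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            Scenario(t_end=10.0, sample_grid=np.array([0.0, 5.0, 4.0]))

    def test_event_time_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            Scenario(t_end=10.0, events=[
                (20.0, VariantSpec("inhibit_EGFR_at_time", {"time": 20.0}))])

    def test_unknown_stimulus_mode_rejected(self):
        with pytest.raises(ValueError):
            Scenario(t_end=10.0, stimulus=("EGF", 1.0, "ramp"))
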
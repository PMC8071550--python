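"""Outcome metrics, checked against closed-form annulus arithmetic."""

import math

import numpy as np
import pytest

from cytodel import (SolverOptions, Trajectory, build_grid, load_preset,
                     simulate)
from cytodel.dosing import DoseRegimen
from cytodel.engine import SolverOptions as _SO
from cytodel.outcomes import (average_inhibition, inhibition_field,
                              inhibitory_effect, max_inhibition,
                              penetration_depth, report,
                              time_of_max_delivery)


def synthetic_trajectory(scenario, times_h, fields, n_shells=50):
    """Assemble a Trajectory from analytically prescribed fields
    (synthetic stand-in for a simulation output)."""
    grid = build_grid(scenario.tissue, n_shells)
    full = {name: np.zeros((len(times_h), n_shells)) for name in
            ("A_int", "R_free", "RC_surf", "A_cyt", "T_free", "TC_cyt")}
    full["T_free"][:] = scenario.target.baseline_concentration_m
    full.update(fields)
    zeros = np.zeros(len(times_h))
    return Trajectory(times_h=np.asarray(times_h, float), fields=full,
                      grid=grid, scenario=scenario, options=_SO(n_shells=n_shells),
                      audit={"influx": zeros, "degraded": zeros,
                             "outflow": zeros},
                      provenance="synthetic")


@pytest.fixture(scope="module")
def scenario():
    return load_preset("tumor_protein_noconv")


class TestInhibitionField:
    def test_pre_dose_zero_everywhere(self, scenario):
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {})
        assert np.all(inhibition_field(traj) == 0.0)

    def test_full_depletion_is_one(self, scenario):
        n = 50
        t_free = np.zeros((2, n))
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {"T_free": t_free})
        assert np.all(inhibition_field(traj) == 1.0)

    def test_zero_baseline_rejected(self, scenario):
        import dataclasses

        target = dataclasses.replace(scenario.target, copies_per_cell=0.0)
        sc = scenario.replace(target=target)
        traj = synthetic_trajectory(sc, [0.0, 1.0], {})
        with pytest.raises(ValueError):
            inhibition_field(traj)

    def test_simulated_inhibition_highest_at_capillary(self, protein_traj):
        inh = inhibition_field(protein_traj)
        i_t = int(np.argmax(average_inhibition(protein_traj)))
        profile = inh[i_t]
        # free target is lowest adjacent to the capillary, rising outward
        assert profile[0] == profile.max()
        assert (np.diff(profile) <= 1e-9).all()


class TestMaxInhibitionAndEffect:
    def test_zero_dose_zero_metrics(self, scenario):
        sc = scenario.replace(regimen=DoseRegimen((), half_life_warm_h=2.55))
        traj = simulate(sc, t_end_h=4.0, options=SolverOptions(n_shells=20))
        assert max_inhibition(traj) == 0.0
        assert inhibitory_effect(traj) == 0.0

    def test_constant_full_inhibition_integrates_to_t_end(self, scenario):
        n, t_end = 50, 24.0
        times = np.linspace(0, t_end, 97)
        t_free = np.zeros((len(times), n))
        traj = synthetic_trajectory(scenario, times, {"T_free": t_free})
        assert max_inhibition(traj) == pytest.approx(1.0)
        assert inhibitory_effect(traj) == pytest.approx(t_end)

    def test_volume_weighting_against_analytic_profile(self, scenario):
        """Inhibition 1 - r/R_K has the closed-form annulus average
        1 - 2(R_K^3 - r_c^3) / (3 R_K (R_K^2 - r_c^2))."""
        n = 400
        grid = build_grid(scenario.tissue, n)
        t0 = scenario.target.baseline_concentration_m
        rk = scenario.tissue.krogh_radius_um
        rc = scenario.tissue.capillary_radius_um
        inh = 1.0 - grid.centers_um / rk
        t_free = t0 * (1.0 - inh)[None, :].repeat(2, axis=0)
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {"T_free": t_free},
                                    n_shells=n)
        exact = 1.0 - 2.0 * (rk**3 - rc**3) / (3.0 * rk * (rk**2 - rc**2))
        assert max_inhibition(traj) == pytest.approx(exact, rel=1e-4)

    def test_effect_monotone_in_horizon(self, tumor_noconv):
        t_short = simulate(tumor_noconv, t_end_h=24.0,
                           options=SolverOptions(n_shells=40))
        t_long = simulate(tumor_noconv, t_end_h=48.0,
                          options=SolverOptions(n_shells=40))
        assert inhibitory_effect(t_long) >= inhibitory_effect(t_short)


class TestTimeOfMaxDelivery:
    def test_zero_dose_returns_nan(self, scenario):
        traj = synthetic_trajectory(scenario, [0.0, 1.0, 2.0], {})
        assert math.isnan(time_of_max_delivery(traj))

    def test_argmin_of_prescribed_minimum(self, scenario):
        times = np.linspace(0, 48, 193)
        t0 = scenario.target.baseline_concentration_m
        # a dip centred at 17 h
        avg = t0 * (1.0 - 0.5 * np.exp(-((times - 17.0) / 6.0) ** 2))
        t_free = avg[:, None].repeat(50, axis=1)
        traj = synthetic_trajectory(scenario, times, {"T_free": t_free})
        assert time_of_max_delivery(traj) == pytest.approx(17.0, abs=0.25)


class TestPenetrationDepth:
    def test_uniform_profile_closed_form(self, scenario):
        """Half the mass of a uniform annular profile lies within
        d = sqrt(r_c^2 + (R_K^2 - r_c^2)/2) - r_c of the wall (68.57 um
        for the 8/108 um geometry)."""
        n = 500
        a = np.full((2, n), 1e-8)
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {"A_int": a},
                                    n_shells=n)
        exact = math.sqrt(8.0**2 + (108.0**2 - 8.0**2) / 2.0) - 8.0
        assert penetration_depth(traj, 0.5, t_h=1.0) == pytest.approx(
            exact, rel=1e-3)

    def test_fraction_one_spans_full_tissue(self, scenario):
        a = np.full((2, 50), 1e-8)
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {"A_int": a})
        assert penetration_depth(traj, 1.0, t_h=1.0) == pytest.approx(100.0)

    def test_no_agent_returns_nan(self, scenario):
        traj = synthetic_trajectory(scenario, [0.0, 1.0], {})
        assert math.isnan(penetration_depth(traj, 0.5, t_h=1.0))

    def test_depth_monotone_in_fraction(self, protein_traj):
        t_peak = time_of_max_delivery(protein_traj)
        depths = [penetration_depth(protein_traj, f, t_h=t_peak)
                  for f in (0.25, 0.5, 0.75, 0.9)]
        assert depths == sorted(depths)


class TestReport:
    def test_report_fields_consistent(self, protein_traj):
        rep = report(protein_traj)
        d = rep.to_dict()
        assert 0.0 < d["max_inhibition"] < 1.0
        assert d["inhibitory_effect_h"] <= protein_traj.times_h[-1]
        assert d["max_inhibition"] >= average_inhibition(protein_traj)[-1]
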
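"""Full simulations: conservation laws, oracles and qualitative shape."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cytodel import (Scenario, SolverOptions, TargetSpec, TissueSpec,
                     make_regimen, simulate)
from cytodel.dosing import DoseRegimen, DoseSpecies, plasma_concentration
from cytodel.params import derive_rates

FAST = SolverOptions(n_shells=40)


class TestZeroDose:
    def test_state_constant_without_dosing(self, tumor_noconv):
        sc = tumor_noconv.replace(
            regimen=DoseRegimen((), half_life_warm_h=2.55))
        traj = simulate(sc, t_end_h=24.0, options=FAST)
        for name, arr in traj.fields.items():
            assert np.allclose(arr, arr[0], rtol=1e-7, atol=1e-18), name


class TestConservation:
    def test_receptor_conservation(self, protein_traj):
        rtot = protein_traj.scenario.tissue.receptor_concentration_m
        total = protein_traj.fields["R_free"] + protein_traj.fields["RC_surf"]
        assert np.abs(total / rtot - 1.0).max() < 1e-6

    def test_non_negativity(self, protein_traj):
        for name, arr in protein_traj.fields.items():
            assert arr.min() >= -1e-9, name

    def test_global_mass_balance(self, protein_traj):
        assert np.abs(protein_traj.mass_balance_residual()).max() < 1e-3

    def test_mass_balance_with_convection_and_drainage(self, tumor_conv):
        traj = simulate(tumor_conv, t_end_h=48.0, options=FAST)
        assert np.abs(traj.mass_balance_residual()).max() < 1e-3
        assert traj.audit["outflow"][-1] > 0.0  # lymphatic loss occurred


class TestWellMixedOracle:
    def test_large_diffusivity_matches_lumped_ode(self, tumor_noconv):
        """With diffusivity large enough to homogenize the annulus the PDE
        must agree with an independently coded well-mixed ODE model."""
        tissue = dataclasses.replace(tumor_noconv.tissue,
                                     interstitial_diffusivity_cm2_s=1e-4)
        sc = tumor_noconv.replace(tissue=tissue)
        traj = simulate(sc, t_end_h=24.0, options=FAST)

        r = derive_rates(sc.agent, tissue, sc.target)
        s_over_v = (2.0 * tissue.capillary_radius_um
                    / (tissue.krogh_radius_um**2 - tissue.capillary_radius_um**2)
                    * 1e4)  # 1/cm
        regimen = sc.regimen

        def rhs(t, y):
            a, rf, c, b, tf, x = y
            cp = plasma_concentration(regimen, DoseSpecies.WARM, t / 3600.0)
            influx = r.permeability_cm_s * (cp - a / r.eps) * s_over_v
            bind = r.kon_r * (a / r.eps) * rf - r.koff_r * c
            internal = r.ke * c
            bind_t = r.kon_t * b * tf - r.koff_t * x
            return [influx - bind,
                    -bind + internal,
                    bind - internal,
                    r.escape * internal / r.phi - r.kdec_cyt * b - bind_t,
                    r.ksyn - r.kdec_target * tf - bind_t,
                    bind_t - r.kdec_cyt * x]

        y0 = [0.0, r.receptor_total_m, 0.0, 0.0, r.target0_m, 0.0]
        sol = solve_ivp(rhs, (0.0, 24 * 3600.0), y0, method="LSODA",
                        t_eval=traj.times_h * 3600.0, rtol=1e-10, atol=1e-16)
        names = ("A_int", "R_free", "RC_surf", "A_cyt", "T_free", "TC_cyt")
        for i, name in enumerate(names):
            avg = traj.grid.average(traj.fields[name])
            scale = np.abs(sol.y[i]).max()
            if scale == 0:
                continue
            assert np.abs(avg - sol.y[i]).max() / scale < 5e-3, name


class TestWallLinearity:
    def test_doubling_permeability_doubles_early_uptake(self, tumor_noconv):
        """At times much shorter than the binding/saturation timescale the
        tissue content is linear in the wall permeability."""
        def early_mass(p_scale):
            tissue = dataclasses.replace(
                tumor_noconv.tissue,
                vascular_permeability_cm_s=p_scale
                * tumor_noconv.tissue.vascular_permeability_cm_s)
            sc = tumor_noconv.replace(tissue=tissue)
            traj = simulate(sc, t_end_h=0.05,
                            options=SolverOptions(n_shells=40,
                                                  output_step_h=0.05))
            return traj.agent_mass_per_length()[-1]

        m1, m2 = early_mass(1.0), early_mass(2.0)
        assert m2 / m1 == pytest.approx(2.0, rel=0.05)


class TestQualitativeShape:
    def test_tissue_agent_peaks_then_decays(self, protein_traj):
        """Total tissue agent after a single dose rises, peaks and falls
        (unimodal) as plasma clears."""
        mass = protein_traj.agent_mass_per_length()
        i_peak = int(np.argmax(mass))
        assert 0 < i_peak < len(mass) - 1
        rising = np.diff(mass[:i_peak + 1])
        falling = np.diff(mass[i_peak:])
        assert (rising > -1e-18).all()
        assert (falling < 1e-18).all()

    def test_monotone_radial_profile_without_convection(self, protein_traj):
        """Diffusion from the capillary yields a non-increasing interstitial
        profile at every time."""
        a = protein_traj.fields["A_int"]
        assert (np.diff(a, axis=1) <= 1e-13).all()

    def test_dose_restart_points_are_handled(self, tumor_noconv):
        reg = make_regimen("repeated", peak_m=1e-6, half_life_h=2.55,
                           interval_h=12.0, n_doses=2)
        sc = tumor_noconv.replace(regimen=reg)
        traj = simulate(sc, t_end_h=36.0, options=FAST)
        # the second bolus re-raises the near-wall concentration
        a_wall = traj.fields["A_int"][:, 0]
        i12 = int(np.searchsorted(traj.times_h, 12.0))
        assert a_wall[i12 + 1] > a_wall[i12 - 1]


class TestModeReductionTrajectory:
    def test_catalytic_zero_kcat_trajectory_matches_binder(self, tumor_noconv):
        from cytodel.params import Mode

        cat = dataclasses.replace(tumor_noconv.agent, mode=Mode.CATALYTIC,
                                  k_cat_per_min=0.0)
        t_binder = simulate(tumor_noconv, t_end_h=24.0, options=FAST)
        t_cat = simulate(tumor_noconv.replace(agent=cat), t_end_h=24.0,
                         options=FAST)
        for name in t_binder.fields:
            a, b = t_binder.fields[name], t_cat.fields[name]
            scale = np.abs(a).max() or 1.0
            assert np.abs(a - b).max() / scale < 1e-6, name
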
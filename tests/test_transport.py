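"""Transport solver tests: closed-form oracles, conservation, interpolation."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from gradlab import (
    EGF,
    VEGF,
    GllGeometry,
    LigandSpec,
    NumericalError,
    TransportParams,
    TranswellGeometry,
    UsageError,
    radius_from_mass,
    sample_field,
    solve_gll,
    solve_transwell,
    steady_state_time,
    stokes_einstein_diffusivity,
    two_compartment_tau_s,
)

C0 = 100.0  # ng/mL loading concentration of the reference ligands


class TestStokesEinstein:
    def test_vegf_literature_value(self):
        # 3.6 nm VEGF at 37 degC water: published estimate 9.0e-7 cm^2/s
        d = stokes_einstein_diffusivity(3.6, 310.0, 6.9e-4)
        assert d == pytest.approx(9.0e-7, rel=0.03)

    def test_hand_evaluated_closed_form(self):
        # k_B*298 / (6*pi*8.9e-4*3.6e-9) m^2/s, evaluated by hand -> cm^2/s
        d = stokes_einstein_diffusivity(3.6, 298.0, 8.9e-4)
        assert d == pytest.approx(6.8125e-7, rel=1e-4)

    def test_inverse_radius_scaling(self):
        assert stokes_einstein_diffusivity(7.2) == pytest.approx(
            stokes_einstein_diffusivity(3.6) / 2.0, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [(0, 310, 7e-4), (3, -1, 7e-4), (3, 310, 0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(UsageError):
            stokes_einstein_diffusivity(*bad)


class TestRadiusFromMass:
    def test_zero_mass_rejected(self):
        with pytest.raises(UsageError):
            radius_from_mass(0.0)

    def test_monotone_in_mass(self):
        masses = [1.0, 6.0, 20.0, 45.0, 100.0]
        radii = [radius_from_mass(m) for m in masses]
        assert all(a < b for a, b in zip(radii, radii[1:]))

    def test_globular_range_at_default_constants(self):
        # cube-root law endpoints: 0.79*6**(1/3) and 0.79*45**(1/3) nm
        assert 1.0 < radius_from_mass(6.0) < 5.0
        assert 1.0 < radius_from_mass(45.0) < 5.0
        assert radius_from_mass(6.0) == pytest.approx(1.4354, rel=1e-3)
        assert radius_from_mass(45.0) == pytest.approx(2.8099, rel=1e-3)


class TestLigandSpec:
    def test_requires_some_transport_property(self):
        with pytest.raises(UsageError):
            LigandSpec("bare")

    def test_resolves_via_stokes_einstein(self):
        lig = LigandSpec("radius-only", hydrodynamic_radius_nm=3.6)
        assert lig.resolve_diffusivity() == pytest.approx(9.0e-7, rel=0.03)

    def test_resolves_via_mass_then_radius(self):
        lig = LigandSpec("mass-only", molecular_weight_kda=38.2)
        assert 1e-7 < lig.resolve_diffusivity() < 1e-5


class TestSolveGll:
    def test_initial_condition(self):
        params = TransportParams(total_time_h=1.0, output_times_h=[0.0, 1.0])
        prof = solve_gll(GllGeometry(), VEGF, params)
        assert prof.source_concentration[0] == pytest.approx(C0)
        assert prof.sink_concentration[0] == 0.0
        assert np.all(prof.concentration[:, 0] == 0.0)

    def test_mass_conserved_to_1e6(self):
        prof = solve_gll(GllGeometry(), VEGF, TransportParams(total_time_h=48.0))
        mass = prof.total_mass_ng()
        assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-6

    def test_equilibrium_mass_balance(self):
        # at t >> L*V_red/(D*A) everything sits at C0*V_src/(V_src+V_sink+V_chan)
        geom = GllGeometry()
        t_eq_h = 10 * 1.9e8 / 3600.0  # ten times the compartment time constant
        params = TransportParams(total_time_h=t_eq_h, output_times_h=[t_eq_h])
        prof = solve_gll(geom, VEGF, params)
        expected = C0 * 98.0 / (98.0 + 98.0 + geom.channel_volume_ul)
        assert expected == pytest.approx(0.499 * C0, rel=1e-3)
        assert prof.source_concentration[-1] == pytest.approx(expected, rel=1e-4)
        assert prof.sink_concentration[-1] == pytest.approx(expected, rel=1e-4)
        assert np.allclose(prof.concentration[:, -1], expected, rtol=1e-4)

    def test_early_time_erfc_oracle(self):
        # before the far end notices, the channel behaves as a semi-infinite
        # medium held at C0: C(x,t) = C0 * erfc(x / (2 sqrt(D t)))
        t_h = 2.0
        params = TransportParams(total_time_h=t_h, output_times_h=[0.0, t_h])
        prof = solve_gll(GllGeometry(), VEGF, params)
        d = VEGF.diffusivity_cm2_s
        exact = C0 * erfc(prof.positions_cm / (2.0 * math.sqrt(d * t_h * 3600.0)))
        mask = exact / C0 > 0.05
        rel = np.abs(prof.concentration[mask, 1] - exact[mask]) / exact[mask]
        assert rel.max() < 0.02

    def test_monotone_profile_without_flow(self):
        prof = solve_gll(GllGeometry(), VEGF, TransportParams(total_time_h=48.0))
        diffs = np.diff(prof.concentration, axis=0)
        assert np.all(diffs <= 1e-9 * C0)

    def test_grid_convergence(self):
        coarse = solve_gll(GllGeometry(), VEGF, TransportParams(
            grid_points=130, total_time_h=24.0, output_times_h=[6.0, 24.0]))
        fine = solve_gll(GllGeometry(), VEGF, TransportParams(
            grid_points=260, total_time_h=24.0, output_times_h=[6.0, 24.0]))
        for k in range(2):
            interp = np.interp(coarse.positions_cm, fine.positions_cm,
                               fine.concentration[:, k])
            assert np.max(np.abs(coarse.concentration[:, k] - interp)) / C0 < 0.01

    def test_fixed_boundary_mode_clamps_reservoirs(self):
        params = TransportParams(total_time_h=24.0, boundary_mode="fixed")
        prof = solve_gll(GllGeometry(), VEGF, params)
        assert np.allclose(prof.source_concentration, C0)
        assert np.allclose(prof.sink_concentration, 0.0)

    def test_advection_shifts_mass_downstream(self):
        slow = solve_gll(GllGeometry(), VEGF, TransportParams(
            total_time_h=6.0, output_times_h=[6.0]))
        moving = solve_gll(GllGeometry(), VEGF, TransportParams(
            bulk_velocity_m_s=2e-7, total_time_h=6.0, output_times_h=[6.0]))
        assert moving.sink_concentration[-1] > slow.sink_concentration[-1]

    def test_egf_spreads_faster_than_vegf(self):
        params = TransportParams(total_time_h=12.0, output_times_h=[12.0])
        v = solve_gll(GllGeometry(), VEGF, params)
        e = solve_gll(GllGeometry(), EGF, params)
        mid = v.positions_cm.size // 2
        assert e.concentration[mid, -1] > v.concentration[mid, -1]


class TestSolveTranswell:
    def test_step_profile_at_t0(self):
        prof = solve_transwell()
        assert prof.source_concentration[0] == pytest.approx(C0)
        assert np.all(prof.concentration[:, 0] == 0.0)
        assert prof.sink_concentration[0] == 0.0

    def test_mass_conserved(self):
        prof = solve_transwell()
        mass = prof.total_mass_ng()
        assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-6

    def test_two_compartment_exponential_oracle(self):
        # compartment difference decays as exp(-t/tau) with
        # tau = (Vt*Vb/(Vt+Vb)) * Th / (D_eff * A); fitted tau within 5%
        geom = TranswellGeometry()
        prof = solve_transwell(geom, VEGF)
        tau = two_compartment_tau_s(geom, VEGF.diffusivity_cm2_s)
        diff = prof.source_concentration - prof.sink_concentration
        t_s = prof.times_h * 3600.0
        sel = (prof.times_h > 0.5) & (diff > 1e-3 * C0)
        slope = np.polyfit(t_s[sel], np.log(diff[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.05)

    def test_equilibrates_to_volume_weighted_mean(self):
        geom = TranswellGeometry()
        tau_h = two_compartment_tau_s(geom, VEGF.diffusivity_cm2_s) / 3600.0
        t_end = 10 * tau_h
        prof = solve_transwell(geom, VEGF, TransportParams(
            grid_points=20, total_time_h=t_end, output_times_h=[t_end]))
        total_volume = (
            prof.source_volume_cm3 + prof.sink_volume_cm3 + prof.cell_volumes_cm3.sum()
        )
        expected = prof.total_mass_ng()[0] / total_volume
        assert prof.source_concentration[-1] == pytest.approx(expected, rel=1e-3)
        assert prof.sink_concentration[-1] == pytest.approx(expected, rel=1e-3)


class TestSteadyStateTime:
    def test_constant_profile_returns_first_time(self):
        prof = solve_transwell()
        # freeze the fields in time: criterion met immediately
        prof.concentration[:, :] = 50.0
        prof.source_concentration[:] = 50.0
        prof.sink_concentration[:] = 50.0
        assert steady_state_time(prof, threshold=0.05, window_h=2.0) == 0.0

    def test_zero_threshold_never_reached(self):
        prof = solve_transwell()
        assert steady_state_time(prof, threshold=0.0, window_h=2.0) is None

    def test_matches_exponential_closed_form(self):
        # top compartment grows as Ceq*(1 - exp(-t/tau)); the first time its
        # relative change over a window w drops below theta solves
        # t* = tau * ln((a + theta)/theta), a = 1 - exp(-w/tau)
        geom = TranswellGeometry()
        prof = solve_transwell(geom, VEGF)
        tau_h = two_compartment_tau_s(geom, VEGF.diffusivity_cm2_s) / 3600.0
        theta, w = 0.05, 2.0
        a = 1.0 - math.exp(-w / tau_h)
        t_star = tau_h * math.log((a + theta) / theta)
        got = steady_state_time(prof, threshold=theta, window_h=w)
        grid_step = prof.times_h[1] - prof.times_h[0]
        assert got == pytest.approx(t_star, abs=2 * grid_step)

    def test_window_exceeding_span_rejected(self):
        prof = solve_transwell()
        with pytest.raises(UsageError):
            steady_state_time(prof, window_h=100.0)


@pytest.fixture(scope="module")
def profile():
    return solve_gll(GllGeometry(), VEGF, TransportParams(total_time_h=12.0))


class TestSampleField:

    def test_grid_node_exact(self, profile):
        c, _ = sample_field(profile, profile.positions_cm[10], profile.times_h[3])
        assert c == pytest.approx(profile.concentration[10, 3], rel=1e-12)

    def test_midpoint_is_mean_of_neighbours(self, profile):
        x = 0.5 * (profile.positions_cm[5] + profile.positions_cm[6])
        c, _ = sample_field(profile, x, profile.times_h[4])
        expected = 0.5 * (profile.concentration[5, 4] + profile.concentration[6, 4])
        assert c == pytest.approx(expected, rel=1e-12)

    def test_linear_profile_constant_gradient(self, profile):
        x = profile.positions_cm
        profile.concentration[:, :] = (3.0 * x)[:, None]
        for pos in (x[1], 0.5 * (x[7] + x[8]), x[-2]):
            _, g = sample_field(profile, pos, 6.0)
            assert g == pytest.approx(3.0, rel=1e-9)

    def test_out_of_domain_rejected(self, profile):
        with pytest.raises(UsageError):
            sample_field(profile, -1.0, 6.0)
        with pytest.raises(UsageError):
            sample_field(profile, profile.positions_cm[3], 999.0)


class TestGeometryInvariants:
    def test_channel_volume_warning(self):
        with pytest.warns(UserWarning, match="channel volume"):
            GllGeometry(reservoir_volume_source_ul=1.0, reservoir_volume_sink_ul=1.0)

    def test_default_porosity_in_unit_interval(self):
        geom = TranswellGeometry()
        assert 0.0 < geom.effective_porosity < 1.0
        # 1e5 pores/cm2 of 8 um pores: eps = 1e5 * pi * (4e-4)**2
        assert geom.effective_porosity == pytest.approx(0.05027, rel=1e-3)

    def test_grid_points_floor(self):
        with pytest.raises(UsageError):
            TransportParams(grid_points=10)
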
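"""Steady-state pump model: equilibria, limits, stall oracles, scans."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epipump import (
    ActiveFluxSpec,
    BathConditions,
    EpitheliumParams,
    active_flux,
    osmolarity_scan,
    per_cell_force,
    ppc_curve,
    stall_closed_form_isotonic,
    stall_pressure,
    steady_state,
    zero_pressure_flux,
)
from epipump.pump_model import BracketingError, ConfigurationError, residuals

from conftest import fixed_point_steady_state


class TestSteadyState:
    def test_equilibrium_without_active_flux(self, isotonic):
        p = EpitheliumParams(L_a=3e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        s = steady_state(p, isotonic)
        assert s.J == pytest.approx(0.0, abs=1e-18)
        assert s.c_c == pytest.approx(300.0)
        assert s.c_s == pytest.approx(300.0)
        assert s.P_c == pytest.approx(isotonic.P_a, abs=1e-9)

    def test_solute_free_series_resistance_limit(self):
        p = EpitheliumParams(L_a=3e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        b = BathConditions(c_a=0.0, c_b=0.0, P_a=100.0, P_b=0.0)
        # three equal conductances in series: (3/L)^-1 * 100 = 1e-8 m/s
        assert steady_state(p, b).J == pytest.approx(1e-8, rel=1e-12)

    def test_passive_flux_is_linear_in_pressure(self):
        p = EpitheliumParams(L_a=2e-10, L_b=5e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        L_ser = p.L_series
        for dp in (-50.0, 10.0, 200.0):
            b = BathConditions(c_a=0.0, c_b=0.0, P_a=0.0, P_b=dp)
            assert steady_state(p, b).J == pytest.approx(-L_ser * dp, rel=1e-9)

    def test_matches_damped_fixed_point_oracle(self, mdck_reference):
        params, baths = mdck_reference
        s = steady_state(params, baths)
        c_c, P_c, c_s, P_s, J = fixed_point_steady_state(params, baths)
        assert J > 0
        assert s.J == pytest.approx(J, rel=1e-6)
        assert s.c_c == pytest.approx(c_c, rel=1e-6)
        assert s.c_s == pytest.approx(c_s, rel=1e-6)
        assert s.P_s == pytest.approx(P_s, rel=1e-6)

    def test_conservation_residuals_below_tolerance(self, mdck_reference, oracle_params):
        params, baths = mdck_reference
        for p, b in [
            (params, baths),
            (oracle_params, BathConditions(c_a=300, c_b=300, P_a=0, P_b=120)),
            (oracle_params, BathConditions(c_a=250, c_b=300, P_a=30, P_b=0)),
        ]:
            s = steady_state(p, b)
            res = residuals(p, b, s)
            assert np.linalg.norm(list(res.values())) < 1e-10

    def test_sign_symmetry_under_mirroring(self, oracle_params):
        """Orientation flip negates the stall exactly and the flux under
        mirrored pressures (up to the tiny advective asymmetry of the
        serial cleft, ~J/(k_d+G) in relative terms)."""
        sec = replace(oracle_params, orientation="secretory")
        b = BathConditions(c_a=300.0, c_b=300.0, P_a=10.0, P_b=0.0)
        b_mirror = BathConditions(c_a=300.0, c_b=300.0, P_a=0.0, P_b=10.0)
        assert steady_state(sec, b_mirror).J == pytest.approx(
            -steady_state(oracle_params, b).J, rel=1e-3
        )
        assert stall_pressure(sec, BathConditions()) == pytest.approx(
            -stall_pressure(oracle_params, BathConditions()), rel=1e-9
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            EpitheliumParams(L_a=-1e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        with pytest.raises(ConfigurationError):
            EpitheliumParams(L_a=1e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5,
                             sigma_r=1.5)
        with pytest.raises(ConfigurationError):
            BathConditions(c_a=-1.0)


class TestActiveFlux:
    def test_constant_variant_ignores_baths(self):
        spec = ActiveFluxSpec(variant="constant", A0=3e-6)
        assert active_flux(spec, BathConditions(c_a=100, c_b=400)) == 3e-6

    def test_osmotic_linear_identity_at_equal_osmolarity(self):
        spec = ActiveFluxSpec(variant="osmotic_linear", A0=3e-6, alpha=-1.0, Pi_ref=7.7e5)
        assert active_flux(spec, BathConditions(c_a=300, c_b=300)) == 3e-6

    def test_osmotic_linear_scales_with_gradient(self):
        spec = ActiveFluxSpec(variant="osmotic_linear", A0=2e-6, alpha=-1.0, Pi_ref=773100.0)
        # 20% apical dilution at RT sigma = 2577: factor 1 + 0.2*2577*300/Pi_ref
        a = active_flux(spec, BathConditions(c_a=240, c_b=300), rt_sigma=2577.0)
        assert a == pytest.approx(2e-6 * (1 + 2577.0 * 60 / 773100.0), rel=1e-12)

    def test_apical_pressure_extinguishes_at_saturation(self):
        spec = ActiveFluxSpec(variant="apical_pressure", A0=3e-6, P_sat=500.0)
        assert active_flux(spec, BathConditions(P_a=500.0)) == 0.0
        assert active_flux(spec, BathConditions(P_a=1000.0)) == 0.0  # clipped
        assert active_flux(spec, BathConditions(P_a=250.0)) == pytest.approx(1.5e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            ActiveFluxSpec(variant="quadratic")


class TestStallPressure:
    def test_closed_form_oracle_value(self, oracle_params, isotonic):
        # RT sigma A / (k_d + g_a g_b/(g_a+g_b)) = 2577*2.5e-6/3.2e-5
        assert stall_closed_form_isotonic(oracle_params) == pytest.approx(201.328125)
        assert stall_pressure(oracle_params, isotonic) == pytest.approx(201.328125, rel=1e-9)

    def test_zero_active_flux_gives_zero_stall(self, isotonic):
        p = EpitheliumParams(L_a=3e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        assert stall_pressure(p, isotonic) == pytest.approx(0.0, abs=1e-9)
        assert stall_closed_form_isotonic(p) == 0.0

    def test_closed_form_linear_in_active_flux(self, oracle_params):
        doubled = replace(
            oracle_params, active=replace(oracle_params.active, A0=2 * oracle_params.active.A0)
        )
        assert stall_closed_form_isotonic(doubled) == pytest.approx(
            2 * stall_closed_form_isotonic(oracle_params)
        )

    def test_secretory_orientation_flips_sign(self, oracle_params, isotonic):
        sec = replace(
            oracle_params,
            orientation="secretory",
            active=replace(oracle_params.active, A0=3.72e-6),
        )
        stall = stall_pressure(sec, isotonic)
        assert stall == pytest.approx(stall_closed_form_isotonic(sec), rel=1e-9)
        assert stall == pytest.approx(-300.0, rel=2e-3)

    def test_numeric_matches_closed_form_random_sweep(self, isotonic):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = EpitheliumParams(
                L_a=10 ** rng.uniform(-10.5, -9.0),
                L_b=10 ** rng.uniform(-10.5, -9.0),
                K_s=10 ** rng.uniform(-10.5, -9.0),
                g_a=10 ** rng.uniform(-5.5, -4.0),
                g_b=10 ** rng.uniform(-5.5, -4.0),
                k_d=10 ** rng.uniform(-6.5, -5.0),
                active=ActiveFluxSpec(variant="constant", A0=10 ** rng.uniform(-6.5, -5.5)),
            )
            expected = stall_closed_form_isotonic(p)
            assert abs(stall_pressure(p, isotonic) - expected) / abs(expected) < 1e-6

    def test_closed_form_contract_requires_constant_variant(self, oracle_params):
        p = replace(oracle_params, active=ActiveFluxSpec(variant="osmotic_linear", A0=1e-6))
        with pytest.raises(ConfigurationError):
            stall_closed_form_isotonic(p)

    def test_bracketing_failure_reports_endpoints(self, isotonic):
        # a pure passive filter with enormous bracket demand: J never crosses
        # zero away from dP=0, so shrink the search to a one-sided interval
        p = EpitheliumParams(L_a=3e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5,
                             active=ActiveFluxSpec(variant="constant", A0=2.5e-6))
        with pytest.raises(BracketingError) as err:
            stall_pressure(p, isotonic, bracket=(500.0, 600.0))
        assert err.value.endpoints


class TestPPCAndScans:
    def test_ppc_strictly_decreasing_with_one_sign_change(self, mdck_reference):
        params, baths = mdck_reference
        curve = ppc_curve(params, baths, np.linspace(-50, 300, 36))
        assert np.all(np.diff(curve.J) < 0)
        assert np.sum(np.diff(np.sign(curve.J)) != 0) == 1

    def test_passive_ppc_is_line_through_origin(self, isotonic):
        p = EpitheliumParams(L_a=3e-10, L_b=3e-10, K_s=3e-10, g_a=1e-5, g_b=1e-5, k_d=1e-5)
        grid = np.linspace(-100, 100, 11)
        curve = ppc_curve(p, BathConditions(c_a=0.0, c_b=0.0), grid)
        np.testing.assert_allclose(curve.J, -p.L_series * grid, rtol=1e-9, atol=1e-22)

    def test_normalized_ppc_peaks_at_one(self, mdck_reference):
        params, baths = mdck_reference
        curve = ppc_curve(params, baths, np.linspace(-50, 150, 21), normalize=True)
        assert curve.J.max() == pytest.approx(1.0)
        assert np.argmax(curve.J) == 0  # maximal flux at the most negative dP

    def test_zero_pressure_flux_consistency(self, mdck_reference, cystic_reference):
        params, baths = mdck_reference
        j0 = zero_pressure_flux(params, baths)
        curve = ppc_curve(params, baths, [-10.0, 0.0, 10.0])
        assert j0 == pytest.approx(curve.J[1], rel=1e-12)
        assert j0 > 0
        c_params, c_baths = cystic_reference
        assert zero_pressure_flux(c_params, c_baths) < 0

    def test_osmolarity_scan_identity_at_zero_fraction(self, mdck_reference):
        params, baths = mdck_reference
        table = osmolarity_scan(params, baths, [0.0])
        assert table.loc[0, "J0"] == pytest.approx(zero_pressure_flux(params, baths))
        assert table.loc[0, "deltaP_star"] == pytest.approx(stall_pressure(params, baths))

    def test_osmotic_linear_stall_shifts_with_dilution(self, mdck_reference):
        params, baths = mdck_reference
        p = replace(params, active=ActiveFluxSpec(
            variant="osmotic_linear", A0=params.active.A0, alpha=-1.0, Pi_ref=773100.0))
        table = osmolarity_scan(p, baths, [0.0, 0.1, 0.2, 0.5])
        assert np.all(np.diff(table["deltaP_star"]) > 0)

    def test_apical_pressure_stall_converges_while_flux_shifts(self, mdck_reference):
        params, baths = mdck_reference
        p = replace(params, active=ActiveFluxSpec(
            variant="apical_pressure", A0=params.active.A0, P_sat=3000.0))
        table = osmolarity_scan(p, baths, [0.0, 0.1, 0.2, 0.5])
        stall_spread = table["deltaP_star"].max() - table["deltaP_star"].min()
        assert stall_spread / abs(table["deltaP_star"].iloc[0]) < 0.05
        j0 = table["J0"]
        assert (j0.max() - j0.min()) / abs(j0.iloc[0]) > 0.20

    def test_dilution_fraction_out_of_range_rejected(self, mdck_reference):
        params, baths = mdck_reference
        with pytest.raises(ConfigurationError):
            osmolarity_scan(params, baths, [0.95])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    la=st.floats(1e-11, 1e-9), lb=st.floats(1e-11, 1e-9), ks=st.floats(1e-11, 1e-9),
    ga=st.floats(1e-6, 1e-4), gb=st.floats(1e-6, 1e-4), kd=st.floats(1e-8, 1e-5),
    a0=st.floats(0.0, 1e-5),
)
def test_flux_nonincreasing_in_pressure_gradient(la, lb, ks, ga, gb, kd, a0):
    """J(dP) never increases with the opposing pressure gradient."""
    p = EpitheliumParams(L_a=la, L_b=lb, K_s=ks, g_a=ga, g_b=gb, k_d=kd,
                         active=ActiveFluxSpec(variant="constant", A0=a0))
    b = BathConditions()
    grid = np.linspace(-200, 400, 13)
    j = [steady_state(p, BathConditions(c_a=300, c_b=300, P_a=0, P_b=dp)).J for dp in grid]
    assert np.all(np.diff(j) <= 1e-20)


class TestPerCellForce:
    @pytest.mark.parametrize(
        "stall, area, expected",
        [(250.0, 400e-12, 100e-9), (100.0, 300e-12, 30e-9), (0.0, 400e-12, 0.0)],
    )
    def test_force_examples(self, stall, area, expected):
        assert per_cell_force(stall, area) == pytest.approx(expected)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ConfigurationError):
            per_cell_force(100.0, 0.0)
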
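"""Unit and property tests of the contractile-element primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcomech.contractile import (
    MetaboliteState,
    ModeOverlay,
    RateSet,
    SarcomereState,
    StrainState,
    ThinFilamentState,
    XBState,
    active_tension,
    apply_overlay,
    atpase_rate,
    compute_rates,
    hfmd,
    jcb_flux,
    passive_and_length_dynamics,
    steady_state_duty_fractions,
    strain_derivatives,
    temperature_factor,
    thin_filament_derivatives,
    xb_derivatives,
)


class TestTemperatureFactor:
    @pytest.mark.parametrize("Q,T,expected", [
        (6.25, 37.0, 1.0),          # exponent zero at body temperature
        (1.0, 12.3, 1.0),           # unit base
        (2.5, 37.0, 1.0),
        (6.25, 27.0, 0.16),         # 6.25**-1
        (6.25, 47.0, 6.25),
    ])
    def test_values(self, Q, T, expected):
        assert temperature_factor(Q, T) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_base(self):
        with pytest.raises(ValueError):
            temperature_factor(0.0, 37.0)
        with pytest.raises(ValueError):
            temperature_factor(-2.0, 37.0)


class TestStrainModulation:
    def test_zero_strain_is_neutral(self, params):
        assert hfmd(StrainState(0.0, params.x0), params) == 1.0

    def test_positive_strain_slows_isomerisation(self, params):
        assert hfmd(StrainState(params.x0, params.x0), params) == pytest.approx(
            math.exp(-5.0), rel=1e-12)

    def test_negative_strain_speeds_isomerisation(self, params):
        assert hfmd(StrainState(-params.x0, params.x0), params) == pytest.approx(
            math.exp(5.0), rel=1e-12)


class TestComputeRates:
    def test_reference_metabolite_limit(self, params, metabolites):
        """At reference metabolites every metabolite factor is 1, so the rate
        set reduces to the non-metabolic crossbridge formulation."""
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params, SL=2.3)
        x = params.xbmodsp
        assert r.ap1 == pytest.approx(params.fap * x, rel=1e-12)      # 100
        assert r.ap2 == pytest.approx(params.hf * x, rel=1e-12)       # 400
        assert r.am2 == pytest.approx(params.hb * x, rel=1e-12)       # 80
        assert r.ap3 == pytest.approx(params.gxb * x, rel=1e-12)      # 14
        # full overlap at SL 2.3 -> gapslmd = 1
        assert r.am1 == pytest.approx(params.gap * x, rel=1e-4)
        assert r.am3 < 1e-6  # thermodynamic reverse flux is negligible

    def test_mava_forward_activation_scaling(self, params, metabolites):
        """The Mavacamten coefficient A = 0.26 scales the attachment rate."""
        base = compute_rates(XBState(), StrainState(0.0, params.x0),
                             metabolites, params)
        ov = ModeOverlay(name="A_only", A=0.26)
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params, ov)
        assert r.ap1 == pytest.approx(0.26 * base.ap1, rel=1e-12)

    def test_adp_dissociation_factor_unity_at_reference(self, metabolites):
        """MgADP at its reference leaves the detachment rate untouched."""
        assert metabolites.MgADP == metabolites.MgADP_ref
        kd = metabolites.kdADP
        factor = (kd + metabolites.MgADP_ref) / (kd + metabolites.MgADP)
        assert factor == 1.0

    def test_elevated_adp_slows_detachment_and_speeds_reverse_stroke(
            self, params, metabolites):
        base = compute_rates(XBState(), StrainState(0.0, params.x0),
                             metabolites, params)
        hi = MetaboliteState(MgADP=72e-3)
        r = compute_rates(XBState(), StrainState(0.0, params.x0), hi, params)
        assert r.ap3 < base.ap3
        assert r.am2 > base.am2

    def test_rejects_negative_metabolites(self, params):
        with pytest.raises(ValueError):
            MetaboliteState(Pi=-1.0)

    def test_rejects_nan_strain(self, params, metabolites):
        with pytest.raises(ValueError):
            compute_rates(XBState(), StrainState(float("nan"), params.x0),
                          metabolites, params)


def _clamped_matrix(r: RateSet) -> np.ndarray:
    """Generator matrix of the 3-state (P, preR, pstR) clamped cycle."""
    return np.array([
        [-(r.ap1 + r.am3), r.am1, r.ap3],
        [r.ap1, -(r.am1 + r.ap2), r.am2],
        [r.am3, r.ap2, -(r.am2 + r.ap3)],
    ])


def _nullspace_fractions(r: RateSet) -> tuple[float, float]:
    """Independent oracle: stationary distribution by linear solve."""
    A = _clamped_matrix(r)
    M = np.vstack([A[:-1], np.ones(3)])
    b = np.array([0.0, 0.0, 1.0])
    pi = np.linalg.solve(M, b)
    return pi[1], pi[2]


class TestDutyFractions:
    def test_matches_linear_solve_oracle_on_random_rates(self, rng):
        """100 random positive rate sets vs the null-space solution."""
        for _ in range(100):
            vals = 10.0 ** rng.uniform(-2, 3, size=6)
            r = RateSet(knpT=1, kpnT=1, ap1=vals[0], ap2=vals[1], ap3=vals[2],
                        am1=vals[3], am2=vals[4], am3=vals[5])
            pre, pst = steady_state_duty_fractions(r)
            pre_o, pst_o = _nullspace_fractions(r)
            assert abs(pre - pre_o) < 1e-9
            assert abs(pst - pst_o) < 1e-9

    def test_equal_rates_give_equal_fractions(self):
        r = RateSet(knpT=1, kpnT=1, ap1=7.0, ap2=7.0, ap3=7.0,
                    am1=7.0, am2=7.0, am3=7.0)
        pre, pst = steady_state_duty_fractions(r)
        assert pre == pytest.approx(pst, rel=1e-12)
        assert pre == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_zero_numerator_gives_zero_fraction(self):
        r = RateSet(knpT=1, kpnT=1, ap1=0.0, ap2=5.0, ap3=3.0,
                    am1=2.0, am2=4.0, am3=0.0)
        pre, _ = steady_state_duty_fractions(r)
        assert pre == 0.0

    def test_degenerate_all_zero_rejected(self):
        r = RateSet(knpT=1, kpnT=1, ap1=0, ap2=0, ap3=0, am1=0, am2=0, am3=0)
        with pytest.raises(ValueError):
            steady_state_duty_fractions(r)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-2, max_value=1e3), min_size=6,
                    max_size=6))
    def test_property_matches_oracle(self, vals):
        r = RateSet(knpT=1, kpnT=1, ap1=vals[0], ap2=vals[1], ap3=vals[2],
                    am1=vals[3], am2=vals[4], am3=vals[5])
        pre, pst = steady_state_duty_fractions(r)
        pre_o, pst_o = _nullspace_fractions(r)
        assert pre == pytest.approx(pre_o, abs=1e-9)
        assert pst == pytest.approx(pst_o, abs=1e-9)


class TestXBDerivatives:
    def test_single_influx_from_nonpermissive(self, params, metabolites):
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        dp, dpre, dpst = xb_derivatives(XBState(0.0, 0.0, 0.0), r)
        assert dpre == 0.0
        assert dpst == 0.0
        assert dp == pytest.approx(r.knpT, rel=1e-12)

    def test_occupancy_conserved_including_derived_state(self, params,
                                                         metabolites, rng):
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            xb = XBState(f[0], f[1], f[2])
            dp, dpre, dpst = xb_derivatives(xb, r)
            dn = -(dp + dpre + dpst)  # N_XB is algebraic
            assert dp + dpre + dpst + dn == 0.0

    def test_steady_state_of_clamped_cycle_has_zero_derivatives(
            self, params, metabolites):
        """States set to the linear-solve stationary point of the clamped
        3-state cycle (scaled into the permissive pool) are stationary."""
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        A = _clamped_matrix(r)
        M = np.vstack([A[:-1], np.ones(3)])
        pi = np.linalg.solve(M, np.array([0.0, 0.0, 1.0]))
        # add the N <-> P exchange: scale so that knpT*N == outflow from pool
        # with N chosen to balance P: N = kpnT*P/knpT
        n = r.kpnT * pi[0] / r.knpT
        scale = 1.0 / (pi.sum() + n)
        xb = XBState(pi[0] * scale, pi[1] * scale, pi[2] * scale)
        dp, dpre, dpst = xb_derivatives(xb, r)
        assert abs(dp) < 1e-9
        assert abs(dpre) < 1e-9
        assert abs(dpst) < 1e-9


class TestStrainDerivatives:
    def test_isometric_equilibrium_strains_are_stationary(self, params,
                                                          metabolites):
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        dpre, dpst = strain_derivatives(StrainState(0.0, params.x0), r, 0.0,
                                        params)
        assert dpre == 0.0
        assert dpst == 0.0

    def test_motion_term_is_half_filament_velocity(self, params, metabolites):
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        v = -1.75
        d0 = strain_derivatives(StrainState(0.0, params.x0), r, 0.0, params)
        d1 = strain_derivatives(StrainState(0.0, params.x0), r, v, params)
        assert d1[0] - d0[0] == pytest.approx(0.5 * v, rel=1e-12)
        assert d1[1] - d0[1] == pytest.approx(0.5 * v, rel=1e-12)

    def test_generic_inputs_match_direct_formula(self, params, metabolites,
                                                 rng):
        """Independent evaluation of the strain rate law."""
        for _ in range(10):
            xpre = rng.uniform(-0.002, 0.002)
            xpst = rng.uniform(0.002, 0.012)
            v = rng.uniform(-2, 2)
            strain = StrainState(xpre, xpst)
            r = compute_rates(XBState(), strain, MetaboliteState(), params)
            pre_f, pst_f = steady_state_duty_fractions(r)
            exp_pre = 0.5 * v + params.phi / pre_f * (
                -r.ap1 * xpre + r.am2 * (xpst - params.x0 - xpre))
            exp_pst = 0.5 * v + params.phi / pst_f * (
                r.ap2 * (xpre + params.x0 - xpst))
            got = strain_derivatives(strain, r, v, params)
            assert got[0] == pytest.approx(exp_pre, rel=1e-9)
            assert got[1] == pytest.approx(exp_pst, rel=1e-9)


class TestThinFilament:
    def test_zero_calcium_means_pure_decay(self, params, metabolites):
        tf = ThinFilamentState(0.4, 0.6)
        d = thin_filament_derivatives(0.0, tf, metabolites, params)
        assert d["dTropCaL"] < 0
        assert d["dTropCaH"] < 0

    def test_half_activation_at_perm50(self, params, metabolites):
        """With the regulatory occupancy at perm50 the cooperative gate sits
        at its half-activation point: permtot = sqrt(1/2)."""
        occ = params.perm50
        tf = ThinFilamentState(occ, occ)  # SL-weighting then gives Tropreg=occ
        d = thin_filament_derivatives(1e-4, tf, metabolites, params)
        expected = params.knp * math.sqrt(0.5)
        assert d["knpT"] == pytest.approx(expected, rel=1e-9)

    def test_acidosis_reduces_calcium_association(self, params, metabolites):
        tf = ThinFilamentState(0.1, 0.1)
        d_ref = thin_filament_derivatives(5e-4, tf, metabolites, params)
        acidic = MetaboliteState(pH=6.5)
        d_acid = thin_filament_derivatives(5e-4, tf, acidic, params)
        assert d_acid["dTropCaL"] < d_ref["dTropCaL"]

    def test_negative_calcium_rejected(self, params, metabolites):
        with pytest.raises(ValueError):
            thin_filament_derivatives(-1e-4, ThinFilamentState(), metabolites,
                                      params)


class TestTensionAndFluxes:
    def test_no_strong_binding_no_tension(self, params):
        t = active_tension(XBState(0.5, 0.0, 0.0), StrainState(0.0, params.x0),
                           params)
        assert t == 0.0

    def test_tension_linear_in_kxb(self, params):
        from dataclasses import replace
        xb = XBState(0.1, 0.2, 0.3)
        strain = StrainState(0.001, 0.008)
        t1 = active_tension(xb, strain, params)
        t2 = active_tension(xb, strain, replace(params, kxb=2 * params.kxb))
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_atpase_zero_without_poststroke_occupancy(self, params,
                                                      metabolites):
        r = compute_rates(XBState(), StrainState(0.0, params.x0), metabolites,
                          params)
        assert atpase_rate(XBState(0.3, 0.0, 0.0), r) == 0.0

    def test_jcb_zero_for_stationary_troponin(self, params):
        assert jcb_flux(0.0, 0.0, 2.2, 0.0, ThinFilamentState(0.2, 0.3),
                        params) == 0.0


class TestLengthDynamics:
    def test_rest_length_without_tension_is_equilibrium(self, params):
        s = SarcomereState(SL=params.SL0, dSL_dt=0.0)
        dsl, dsld = passive_and_length_dynamics(s, 0.0, params)
        assert dsl == 0.0
        assert dsld == pytest.approx(0.0, abs=1e-12)

    def test_isometric_flag_freezes_length(self, params):
        s = SarcomereState(SL=2.0, dSL_dt=0.0, isometric=True)
        assert passive_and_length_dynamics(s, 5.0, params) == (0.0, 0.0)

    def test_collapsed_length_aborts(self, params):
        with pytest.raises(ValueError):
            SarcomereState(SL=-0.1)


class TestOverlayApplication:
    def test_om_doubles_forward_isomerisation_base(self, params):
        from sarcomech.modes import load_overlay
        p2 = apply_overlay(params, load_overlay("om_1uM"))
        assert p2.hf == pytest.approx(4000.0)

    def test_bleb_leaves_calcium_on_rate_untouched(self, params):
        from sarcomech.modes import load_overlay
        p2 = apply_overlay(params, load_overlay("bleb_5uM"))
        assert p2.kon == params.kon

    def test_control_overlay_is_identity(self, params):
        p2 = apply_overlay(params, ModeOverlay())
        assert p2 == params
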
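import math

import numpy as np
import pytest

from kineticgfr import (
    KineticParams,
    UnsupportedBranchError,
    ckd_slope,
    dcr_dgfr,
    dcr_dgfr_general,
    dcr_dgfr_limit_both_zero,
    dcr_dgfr_limit_dv0,
    dcr_dgfr_limit_gfr_eq_neg_dv,
    dcr_dvolrate,
    finite_difference,
    sign_scan,
)
from kineticgfr.sensitivity import (
    BRANCH_BOTH_ZERO,
    BRANCH_DV0,
    BRANCH_GENERAL,
    BRANCH_GFR_NEG_DV,
)
from conftest import random_valid_params


class TestWorkedSlopes:
    def test_low_cr_slope_shallow(self, low_cr_scenario):
        result = dcr_dgfr(low_cr_scenario, 24.0)
        assert result.branch == BRANCH_GENERAL
        assert result.value == pytest.approx(-0.009722536, abs=5e-10)

    def test_high_cr_slope_steep(self, high_cr_scenario):
        result = dcr_dgfr(high_cr_scenario, 24.0)
        assert result.value == pytest.approx(-0.217521268, abs=5e-10)

    def test_high_cr_magnitude_exceeds_low_cr(self, low_cr_scenario, high_cr_scenario):
        low = abs(dcr_dgfr(low_cr_scenario, 24.0).value)
        high = abs(dcr_dgfr(high_cr_scenario, 24.0).value)
        assert high > low

    def test_reported_unit_is_internal_times_0_06(self, low_cr_scenario):
        result = dcr_dgfr(low_cr_scenario, 24.0)
        assert result.value == pytest.approx(result.value_per_l_h * 0.06, rel=1e-15)


class TestBranchDispatchAndLimits:
    def test_zero_at_t0_on_every_branch(self):
        cases = [
            KineticParams(cr0=1.0, gen=5.4, gfr_k=5.4, v0=42.0, dv_dt=0.25),
            KineticParams(cr0=1.0, gen=5.4, gfr_k=5.4, v0=42.0, dv_dt=0.0),
            KineticParams(cr0=1.0, gen=5.4, gfr_k=0.25, v0=42.0, dv_dt=-0.25),
            KineticParams(cr0=1.0, gen=5.4, gfr_k=0.0, v0=42.0, dv_dt=0.0),
        ]
        branches = {dcr_dgfr(p, 0.0).branch for p in cases}
        assert branches == {
            BRANCH_GENERAL, BRANCH_DV0, BRANCH_GFR_NEG_DV, BRANCH_BOTH_ZERO,
        }
        for p in cases:
            assert dcr_dgfr(p, 0.0).value == pytest.approx(0.0, abs=1e-15)

    def test_zero_total_clearance_limit_matches_symbolic_value(self):
        # frozen from an independent computer-algebra limit of the
        # general derivative as GFR_K -> -dV/dt
        p = KineticParams(cr0=1.0, gen=5.4, gfr_k=0.25, v0=42.0, dv_dt=-0.25)
        result = dcr_dgfr(p, 24.0)
        assert result.branch == BRANCH_GFR_NEG_DV
        assert result.value_per_l_h == pytest.approx(-1.64313978564913, rel=1e-12)
        assert result.value == pytest.approx(-0.0985883871389477, rel=1e-12)

    def test_both_zero_limit_hand_value(self):
        # -(24/42)*(5.4*24/84 + 1) by hand, then x0.06 for per-mL/min
        p = KineticParams(cr0=1.0, gen=5.4, gfr_k=0.0, v0=42.0, dv_dt=0.0)
        result = dcr_dgfr(p, 24.0)
        assert result.branch == BRANCH_BOTH_ZERO
        assert result.value_per_l_h == pytest.approx(-1.45306122448980, rel=1e-12)
        assert result.value == pytest.approx(-1.45306122448980 * 0.06, rel=1e-12)

    def test_fixed_volume_limit_at_steady_state_start(self):
        # when cr0 = Gen/g the first bracket vanishes by construction
        g, gen, v0, t = 3.0, 5.4, 42.0, 24.0
        p = KineticParams(cr0=gen / g, gen=gen, gfr_k=g, v0=v0, dv_dt=0.0)
        expected = -(1.0 - math.exp(-g * t / v0)) * gen / g**2
        result = dcr_dgfr(p, t)
        assert result.branch == BRANCH_DV0
        assert result.value_per_l_h == pytest.approx(expected, rel=1e-12)
        assert result.value < 0

    def test_gfr_zero_routes_away_from_fixed_volume_branch(self):
        p = KineticParams(cr0=1.0, gen=5.4, gfr_k=0.0, v0=42.0, dv_dt=0.0)
        assert dcr_dgfr_limit_dv0(p, 24.0).branch == BRANCH_BOTH_ZERO

    def test_dv_zero_routes_away_from_total_clearance_branch(self):
        p = KineticParams(cr0=1.0, gen=5.4, gfr_k=0.0, v0=42.0, dv_dt=0.0)
        assert dcr_dgfr_limit_gfr_eq_neg_dv(p, 24.0).branch == BRANCH_BOTH_ZERO

    @pytest.mark.parametrize("offset", [1e-9, -1e-9])
    def test_continuity_general_vs_fixed_volume_limit(self, offset):
        rng = np.random.default_rng(23)
        for _ in range(30):
            p, t = random_valid_params(rng)
            p0 = KineticParams(cr0=p.cr0, gen=p.gen, gfr_k=max(p.gfr_k, 0.05),
                               v0=p.v0, dv_dt=0.0)
            pg = KineticParams(cr0=p0.cr0, gen=p0.gen, gfr_k=p0.gfr_k,
                               v0=p0.v0, dv_dt=offset)
            general = dcr_dgfr_general(pg, t).value
            limit = dcr_dgfr_limit_dv0(p0, t).value
            assert general == pytest.approx(limit, rel=1e-6)

    def test_continuity_general_vs_total_clearance_limit(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            p, t = random_valid_params(rng)
            dv = -0.2 if p.v0 / t > 0.25 else 0.2  # keep rule E satisfied
            p0 = KineticParams(cr0=p.cr0, gen=p.gen, gfr_k=-dv, v0=p.v0, dv_dt=dv)
            pg = KineticParams(cr0=p.cr0, gen=p.gen, gfr_k=-dv + 1e-9,
                               v0=p.v0, dv_dt=dv)
            general = dcr_dgfr_general(pg, t).value
            limit = dcr_dgfr_limit_gfr_eq_neg_dv(p0, t).value
            assert general == pytest.approx(limit, rel=1e-6)

    def test_continuity_general_vs_both_zero_limit(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            p, t = random_valid_params(rng)
            p0 = KineticParams(cr0=p.cr0, gen=p.gen, gfr_k=0.0, v0=p.v0, dv_dt=0.0)
            pg = KineticParams(cr0=p.cr0, gen=p.gen, gfr_k=1e-9, v0=p.v0, dv_dt=1e-9)
            general = dcr_dgfr_general(pg, t).value
            limit = dcr_dgfr_limit_both_zero(p0, t).value
            assert general == pytest.approx(limit, rel=1e-6)


class TestFiniteDifferenceOracle:
    def test_agrees_at_worked_points(self, low_cr_scenario, high_cr_scenario):
        for p in (low_cr_scenario, high_cr_scenario):
            analytic = dcr_dgfr(p, 24.0).value_per_l_h
            numeric = finite_difference("gfr_k", p, 24.0, h=1e-4)
            assert analytic == pytest.approx(numeric, rel=1e-5)

    def test_agrees_on_random_scenarios(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            p, t = random_valid_params(rng, avoid_singular=1e-3)
            analytic = dcr_dgfr(p, t).value_per_l_h
            numeric = finite_difference("gfr_k", p, t, h=1e-5)
            assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-10)

    def test_second_order_convergence(self, high_cr_scenario):
        exact = dcr_dgfr(high_cr_scenario, 24.0).value_per_l_h
        err_h = abs(finite_difference("gfr_k", high_cr_scenario, 24.0, h=2e-3) - exact)
        err_h2 = abs(finite_difference("gfr_k", high_cr_scenario, 24.0, h=1e-3) - exact)
        assert err_h / err_h2 == pytest.approx(4.0, rel=0.15)

    def test_unknown_target_rejected(self, high_cr_scenario):
        with pytest.raises(ValueError):
            finite_difference("v0", high_cr_scenario, 24.0)


class TestVolumeRateSensitivity:
    def test_zero_at_t0(self, vignette):
        assert dcr_dvolrate(vignette, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_matches_symbolic_value_in_vignette(self, vignette):
        # frozen from independent computer-algebra evaluation
        assert dcr_dvolrate(vignette, 24.0) == pytest.approx(
            -1.30609927424759, rel=1e-12
        )

    def test_agrees_with_finite_difference(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            p, t = random_valid_params(rng, avoid_singular=1e-3)
            analytic = dcr_dvolrate(p, t)
            numeric = finite_difference("dv_dt", p, t, h=1e-6)
            assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-9)

    def test_refuses_singular_loci(self):
        p0 = KineticParams(cr0=1.0, gen=5.4, gfr_k=5.4, v0=42.0, dv_dt=0.0)
        with pytest.raises(UnsupportedBranchError):
            dcr_dvolrate(p0, 24.0)
        p1 = KineticParams(cr0=1.0, gen=5.4, gfr_k=0.25, v0=42.0, dv_dt=-0.25)
        with pytest.raises(UnsupportedBranchError):
            dcr_dvolrate(p1, 24.0)


class TestNegativityTheorem:
    def test_random_scan_finds_no_nonnegative_derivative(self):
        report = sign_scan(n=5000, seed=3)
        assert report.n_nonnegative == 0
        assert report.worst_case[2] < 0

    def test_scan_is_deterministic_under_seed(self):
        a = sign_scan(n=500, seed=5)
        b = sign_scan(n=500, seed=5)
        assert a.worst_case == b.worst_case
        assert sign_scan(n=500, seed=6).worst_case != a.worst_case

    def test_extreme_parameter_set_stays_negative(self):
        # high Cr0, small volume, fluid loss, low generation rate
        for gfr_ml_min in np.linspace(0.0, 120.0, 121):
            p = KineticParams.from_clinical(
                cr0=9.0, gen_ml_min=40.0, gfr_k_ml_min=gfr_ml_min,
                v0=30.0, dv_dt_l_h=-0.25,
            )
            assert dcr_dgfr(p, 24.0).value < 0

    def test_negative_across_all_branches(self):
        cases = [
            KineticParams(cr0=2.0, gen=4.0, gfr_k=3.0, v0=40.0, dv_dt=0.2),
            KineticParams(cr0=2.0, gen=4.0, gfr_k=3.0, v0=40.0, dv_dt=0.0),
            KineticParams(cr0=2.0, gen=4.0, gfr_k=0.2, v0=40.0, dv_dt=-0.2),
            KineticParams(cr0=2.0, gen=4.0, gfr_k=0.0, v0=40.0, dv_dt=0.0),
        ]
        for p in cases:
            for t in (0.5, 6.0, 24.0, 72.0):
                assert dcr_dgfr(p, t).value < 0


class TestChronicAcuteConsistency:
    def test_long_run_fixed_volume_slope_approaches_reciprocal_tangent(self):
        # at steady state with constant volume the acute sensitivity
        # collapses to the chronic-disease tangent -Gen/GFR^2
        for gen_ml, gfr_ml in ((90.0, 90.0), (90.0, 10.0), (120.0, 30.0)):
            p = KineticParams.from_clinical(
                cr0=gen_ml / gfr_ml, gen_ml_min=gen_ml, gfr_k_ml_min=gfr_ml,
                v0=42.0, dv_dt_l_h=0.0,
            )
            t_long = 40.0 * p.v0 / p.gfr_k
            acute = dcr_dgfr(p, t_long).value
            assert acute == pytest.approx(ckd_slope(gen_ml, gfr_ml), rel=1e-6)
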
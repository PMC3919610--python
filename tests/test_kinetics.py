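"""Rate laws: Michaelis-Menten insertion, composite velocity, terminator
competition, release-time sampling, and the two shipped calibrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from okacycle import (
    KineticParams,
    calibrate_dgdpnp,
    composite_velocity,
    ddgmp_termination_prob,
    insertion_rate_opposite_C,
    sample_release_time,
)
from okacycle.kinetics import CalibrationError, ParameterError


class TestInsertionRate:
    def test_zero_substrate_gives_zero(self, params):
        assert insertion_rate_opposite_C("dGTP", 0.0, params) == 0.0

    def test_half_saturation(self, params):
        assert insertion_rate_opposite_C("dGTP", params.Km_dGTP, params) == pytest.approx(
            params.v_sat / 2
        )

    def test_dgdpnp_at_30uM_matches_calibration(self, params):
        # independent route: solve the composite-velocity calibration for the
        # per-C rate with a root finder, then compare the direct evaluation
        from scipy.optimize import brentq

        r_c = brentq(
            lambda r: composite_velocity(0.25, r, params) - 23.0, 1e-3, params.v_sat
        )
        direct = insertion_rate_opposite_C("dGDPNP", 30.0, params)
        assert direct == pytest.approx(r_c, rel=1e-9)
        assert direct == pytest.approx(5.93, abs=0.01)

    def test_alpha_lag_multiplier(self, tpl, params):
        import dataclasses

        fast = dataclasses.replace(params, alpha_lag=3.0)
        assert insertion_rate_opposite_C(
            "dGTP", 100.0, fast, fork_coupled=True
        ) == pytest.approx(3 * insertion_rate_opposite_C("dGTP", 100.0, fast))

    def test_unknown_species_rejected(self, params):
        with pytest.raises(ParameterError):
            insertion_rate_opposite_C("dATP", 10.0, params)

    @given(c1=st.floats(0.01, 1000), c2=st.floats(0.01, 1000))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_concentration(self, params, c1, c2):
        lo, hi = sorted((c1, c2))
        if lo == hi:
            return
        assert insertion_rate_opposite_C("dGTP", lo, params) < insertion_rate_opposite_C(
            "dGTP", hi, params
        )


class TestCompositeVelocity:
    def test_no_c_template_runs_saturated(self, params):
        assert composite_velocity(0.0, 1e-6, params) == params.v_sat

    def test_all_c_template_runs_at_r_c(self, params):
        assert composite_velocity(1.0, 10.0, params) == pytest.approx(10.0)

    def test_stalled_r_c_gives_zero_not_error(self, params):
        assert composite_velocity(0.5, 0.0, params) == 0.0

    def test_m13_surrogate_velocity_is_23(self, params):
        r_c = insertion_rate_opposite_C("dGDPNP", 30.0, params)
        assert composite_velocity(0.25, r_c, params) == pytest.approx(23.0)

    def test_minicircle_45pct_c_velocity(self, params):
        r_c = insertion_rate_opposite_C("dGDPNP", 30.0, params)
        assert composite_velocity(0.45, r_c, params) == pytest.approx(13.0, abs=0.1)

    def test_limit_saturates_with_substrate(self, params):
        # saturating dGTP drives the per-C rate to v_sat, and the composite
        # velocity to v_sat exactly
        r_c = insertion_rate_opposite_C("dGTP", 1e9, params)
        assert composite_velocity(0.45, r_c, params) == pytest.approx(
            params.v_sat, rel=1e-6
        )


class TestCalibration:
    def test_recalibration_is_fixed_point(self, params):
        recal = calibrate_dgdpnp(params)
        assert recal.v_chem_dGDPNP == pytest.approx(params.v_chem_dGDPNP)

    def test_infeasible_target_rejected(self, params):
        with pytest.raises(CalibrationError):
            calibrate_dgdpnp(params, target_rate=570.0)

    def test_fold_reduction_rounds_to_25(self, params):
        r_c = insertion_rate_opposite_C("dGDPNP", 30.0, params)
        fold = params.v_sat / composite_velocity(0.25, r_c, params)
        assert round(fold) == 25


class TestTerminationProb:
    def test_no_terminator_no_termination(self, params):
        assert ddgmp_termination_prob(0.0, 100.0, params) == 0.0

    def test_symmetric_competition(self):
        p = KineticParams(f_sel=1.0)
        assert ddgmp_termination_prob(5.0, 5.0, p) == pytest.approx(0.5)

    def test_no_dgtp_forces_termination(self, params):
        assert ddgmp_termination_prob(1.0, 0.0, params) == 1.0

    @given(d1=st.floats(0.0, 50.0), d2=st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_ddgtp(self, params, d1, d2):
        lo, hi = sorted((d1, d2))
        if lo == hi:
            return
        assert ddgmp_termination_prob(lo, 100.0, params) < ddgmp_termination_prob(
            hi, 100.0, params
        )

    def test_f_sel_calibration_against_brute_force_oracle(self, params):
        # oracle: E[min(run, 1500)] by explicit summation over the geometric
        # run-length distribution must equal 750 nt (the 2-fold shortening
        # anchor at 4 uM ddGTP / 100 uM dGTP on the 48.9%-C template)
        p_per_c = ddgmp_termination_prob(4.0, 100.0, params)
        q = (200.0 / 409.0) * p_per_c       # per-nt termination hazard
        spacing = 1500
        expected = sum(
            k * q * (1 - q) ** (k - 1) for k in range(1, spacing)
        ) + spacing * (1 - q) ** (spacing - 1)
        assert expected == pytest.approx(750.0, rel=1e-6)


class TestReleaseTimes:
    def test_signal_release_is_latency(self, params):
        rng = np.random.default_rng(0)
        assert sample_release_time("signal", params, rng) == 0.0

    def test_nick_median_is_two_minutes(self, params):
        rng = np.random.default_rng(42)
        samples = np.array(
            [sample_release_time("nick", params, rng) for _ in range(100_000)]
        )
        assert np.median(samples) == pytest.approx(120.0, rel=0.02)

    @pytest.mark.parametrize("t_half,minutes", [(360.0, 6.0), (660.0, 11.0)])
    def test_stall_half_life_range_covers_6_to_11_min(self, t_half, minutes):
        p = KineticParams(t_half_stall=t_half)
        rng = np.random.default_rng(42)
        samples = np.array(
            [sample_release_time("stall", p, rng) for _ in range(100_000)]
        )
        assert np.median(samples) == pytest.approx(minutes * 60.0, rel=0.02)

    def test_exponential_mean_is_half_life_over_ln2(self, params):
        rng = np.random.default_rng(7)
        samples = np.array(
            [sample_release_time("nick", params, rng) for _ in range(100_000)]
        )
        assert samples.mean() == pytest.approx(120.0 / math.log(2), rel=0.02)

    def test_unknown_context_rejected(self, params):
        with pytest.raises(ParameterError):
            sample_release_time("collision", params, np.random.default_rng(0))


class TestParamValidation:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            KineticParams(v_sat=0.0)

    def test_slow_alpha_warns_but_allowed(self):
        with pytest.warns(UserWarning):
            p = KineticParams(alpha_lag=0.5)
        assert p.alpha_lag == 0.5
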
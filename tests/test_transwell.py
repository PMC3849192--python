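"""Forward transwell model and the steady-state ratio estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpuu import (
    TransportParams,
    TranswellGeometry,
    TranswellMeasurement,
    estimate_steady_state_ratio,
    process_transwell_table,
    ratio_one_hour,
    simulate_transwell,
    sucrose_qc,
)
from kpuu.errors import (
    DegenerateMeasurementError,
    EstimationFailureError,
    InvalidParameterError,
    NonIdentifiableError,
)


def rk4_oracle(params, geom, C_d0, t_end, dt=0.005):
    """Brute-force fixed-step integration of the two-compartment ODEs."""

    def deriv(cd, cr):
        flux = params.PS_in * cd - params.PS_out * cr
        return -flux / geom.V_lum, flux / params.V_app

    cd, cr = C_d0, 0.0
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = deriv(cd, cr)
        k2 = deriv(cd + dt / 2 * k1[0], cr + dt / 2 * k1[1])
        k3 = deriv(cd + dt / 2 * k2[0], cr + dt / 2 * k2[1])
        k4 = deriv(cd + dt * k3[0], cr + dt * k3[1])
        cd += dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6
        cr += dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6
    return cd, cr


class TestSimulate:
    def test_zero_influx_means_no_transfer(self, geom):
        params = TransportParams(PS_in=0.0, PS_out=20.0, V_app=2500.0)
        out = simulate_transwell(params, geom, 2.0, [0, 30, 60, 600])
        assert np.allclose(out["C_donor"], 2.0)
        assert np.allclose(out["C_receiver"], 0.0)

    def test_symmetric_system_splits_mass_evenly(self):
        geom = TranswellGeometry(V_lum=2000.0, V_ab=2000.0)
        params = TransportParams(PS_in=20.0, PS_out=20.0, V_app=2000.0)
        out = simulate_transwell(params, geom, 2.0, [1e6])
        assert out["C_donor"].iloc[0] == pytest.approx(1.0, rel=1e-9)
        assert out["C_receiver"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_closed_form_matches_numerical_integration(self):
        geom = TranswellGeometry(V_lum=1500.0, V_ab=3000.0)
        params = TransportParams(PS_in=10.0, PS_out=20.0, V_app=3000.0)
        out = simulate_transwell(params, geom, 2.0, [60.0])
        cd_ref, cr_ref = rk4_oracle(params, geom, 2.0, 60.0)
        assert out["C_donor"].iloc[0] == pytest.approx(cd_ref, rel=1e-6)
        assert out["C_receiver"].iloc[0] == pytest.approx(cr_ref, rel=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ps_in=st.floats(0.0, 100.0),
        ps_out=st.floats(0.1, 200.0),
        v_lum=st.floats(500.0, 3000.0),
        binding=st.floats(0.0, 5.0),
    )
    def test_mass_conservation(self, ps_in, ps_out, v_lum, binding):
        """The tracked amount V_lum*C_d + V_app*C_r is constant in time."""
        geom = TranswellGeometry(V_lum=v_lum, V_ab=2500.0)
        params = TransportParams(
            PS_in=ps_in, PS_out=ps_out, V_app=2500.0 * (1 + binding)
        )
        out = simulate_transwell(params, geom, 2.0, [0, 10, 60, 300, 3000])
        total = v_lum * out["C_donor"] + params.V_app * out["C_receiver"]
        assert np.allclose(total, v_lum * 2.0, rtol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        ps_in=st.floats(1.0, 60.0),
        ps_out=st.floats(5.0, 120.0),
        binding=st.floats(0.0, 3.0),
    )
    def test_closed_form_equals_integrator_on_random_draws(
        self, geom, ps_in, ps_out, binding
    ):
        params = TransportParams(
            PS_in=ps_in, PS_out=ps_out, V_app=geom.V_ab * (1 + binding)
        )
        out = simulate_transwell(params, geom, 2.0, [60.0])
        cd_ref, cr_ref = rk4_oracle(params, geom, 2.0, 60.0)
        assert out["C_donor"].iloc[0] == pytest.approx(cd_ref, rel=1e-6)
        assert out["C_receiver"].iloc[0] == pytest.approx(cr_ref, rel=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(PS_in=-1.0, PS_out=10.0, V_app=2500.0),
            dict(PS_in=10.0, PS_out=0.0, V_app=2500.0),
            dict(PS_in=10.0, PS_out=10.0, V_app=-5.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            TransportParams(**kwargs)

    def test_unsorted_times_rejected(self, geom):
        params = TransportParams(PS_in=10.0, PS_out=20.0, V_app=2500.0)
        with pytest.raises(InvalidParameterError):
            simulate_transwell(params, geom, 2.0, [60.0, 30.0])


class TestRatioOneHour:
    @pytest.mark.parametrize(
        "c_d_t, c_r_t, expected",
        [(1.0, 0.0, 0.0), (1.3, 1.3, 1.0), (1.6, 0.2, 0.125)],
    )
    def test_ratio(self, c_d_t, c_r_t, expected):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=c_d_t, C_r_t=c_r_t, t=60)
        assert ratio_one_hour(meas) == pytest.approx(expected)

    def test_zero_donor_is_degenerate(self):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=0.0, C_r_t=0.2, t=60)
        with pytest.raises(DegenerateMeasurementError):
            ratio_one_hour(meas)


class TestSteadyStateEstimator:
    def test_reference_example(self, geom):
        """Frozen values from an independent bisection + RK4 receiver oracle."""
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=0.2, t=60)
        est = estimate_steady_state_ratio(meas, geom)
        assert est.lambda_donor == pytest.approx(3.71906e-3, rel=1e-5)
        assert est.mu_receiver == pytest.approx(6.03507e-3, rel=1e-4)
        assert est.R_1h == pytest.approx(0.125)
        assert est.R_ss == pytest.approx(0.36974, rel=1e-4)
        assert est.CL_in == pytest.approx(est.lambda_donor * geom.V_lum)
        assert est.CL_out == pytest.approx(est.mu_receiver * geom.V_ab)

    def test_fitted_receiver_curve_passes_through_measurement(self, geom):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=0.2, t=60)
        est = estimate_steady_state_ratio(meas, geom)
        lam, mu = est.lambda_donor, est.mu_receiver
        scale = est.CL_in * meas.C_d0 / geom.V_ab
        model = scale * (math.exp(-lam * 60) - math.exp(-mu * 60)) / (mu - lam)
        assert abs(model - meas.C_r_t) < 1e-9 * meas.C_d0

    def test_scale_invariance(self, geom):
        base = TranswellMeasurement(C_d0=2.0, C_d_t=1.55, C_r_t=0.18, t=60)
        scaled = TranswellMeasurement(C_d0=14.0, C_d_t=10.85, C_r_t=1.26, t=60)
        a, b = (estimate_steady_state_ratio(m, geom) for m in (base, scaled))
        assert a.lambda_donor == pytest.approx(b.lambda_donor, rel=1e-9)
        assert a.mu_receiver == pytest.approx(b.mu_receiver, rel=1e-8)
        assert a.R_1h == pytest.approx(b.R_1h, rel=1e-9)
        assert a.R_ss == pytest.approx(b.R_ss, rel=1e-8)

    def test_monotone_in_receiver_concentration(self, geom):
        ests = [
            estimate_steady_state_ratio(
                TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=c, t=60), geom
            ).R_ss
            for c in (0.05, 0.1, 0.15, 0.2)
        ]
        assert all(a < b for a, b in zip(ests, ests[1:]))

    def test_degenerate_equal_rates_limit(self, geom):
        """A receiver value engineered so mu == lambda is handled analytically."""
        lam = math.log(2.0 / 1.6) / 60.0
        scale = lam * geom.V_lum * 2.0 / geom.V_ab
        c_r = scale * 60.0 * math.exp(-lam * 60.0)
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=c_r, t=60)
        est = estimate_steady_state_ratio(meas, geom)
        assert est.mu_receiver == pytest.approx(lam, rel=1e-6)

    @pytest.mark.parametrize(
        "lam, mu", [(3e-3, 9e-3), (5e-3, 2e-3), (1e-3, 1e-2)]
    )
    def test_self_consistency_on_own_model_class(self, geom, lam, mu):
        """Data generated by the estimator's model are recovered exactly."""
        C_d0, t = 2.0, 60.0
        C_d_t = C_d0 * math.exp(-lam * t)
        scale = lam * geom.V_lum * C_d0 / geom.V_ab
        C_r_t = scale * (math.exp(-lam * t) - math.exp(-mu * t)) / (mu - lam)
        est = estimate_steady_state_ratio(
            TranswellMeasurement(C_d0=C_d0, C_d_t=C_d_t, C_r_t=C_r_t, t=t), geom
        )
        assert est.lambda_donor == pytest.approx(lam, rel=1e-9)
        assert est.mu_receiver == pytest.approx(mu, rel=1e-7)
        assert est.R_ss == pytest.approx(lam * geom.V_lum / (mu * geom.V_ab), rel=1e-7)

    def test_mass_conserving_data_has_no_finite_exit_rate(self, geom):
        """A binding-free closed-system measurement leaves the receiver exit
        clearance unidentifiable: all donor loss sits in the receiver, so no
        positive exit rate reproduces it and the estimator refuses rather
        than extrapolate."""
        params = TransportParams(PS_in=8.0, PS_out=8.0, V_app=geom.V_ab)
        sim = simulate_transwell(params, geom, 2.0, [60.0])
        meas = TranswellMeasurement(
            C_d0=2.0,
            C_d_t=sim["C_donor"].iloc[0],
            C_r_t=sim["C_receiver"].iloc[0],
            t=60,
        )
        with pytest.raises(EstimationFailureError):
            estimate_steady_state_ratio(meas, geom)

    def test_no_donor_decline_not_identifiable(self, geom):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=2.0, C_r_t=0.1, t=60)
        with pytest.raises(NonIdentifiableError):
            estimate_steady_state_ratio(meas, geom)

    def test_zero_receiver_reports_zero_with_warning(self, geom):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=0.0, t=60)
        with pytest.warns(UserWarning, match="zero"):
            est = estimate_steady_state_ratio(meas, geom)
        assert est.R_ss == 0.0 and est.R_1h == 0.0

    def test_impossible_receiver_concentration_fails(self, geom):
        # more drug in the receiver than the donor ever released
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.99, C_r_t=1.5, t=60)
        with pytest.raises(EstimationFailureError):
            estimate_steady_state_ratio(meas, geom)


class TestSucroseQC:
    @pytest.mark.parametrize(
        "frac, pe, passed",
        [
            (0.0, 0.0, True),
            (0.05, 4.43e-4, True),
            (0.06, 5.32e-4, False),
        ],
    )
    def test_single_timepoint_clearance(self, geom, frac, pe, passed):
        meas = TranswellMeasurement(
            C_d0=2.0, C_d_t=1.6, C_r_t=0.2, t=60, sucrose_receiver_frac=frac
        )
        qc = sucrose_qc(meas, geom)
        assert qc.Pe == pytest.approx(pe, rel=1e-2, abs=1e-12)
        assert qc.passed is passed

    def test_missing_tracer_is_unavailable_not_pass(self, geom):
        meas = TranswellMeasurement(C_d0=2.0, C_d_t=1.6, C_r_t=0.2, t=60)
        qc = sucrose_qc(meas, geom)
        assert qc.Pe is None and qc.passed is None and not qc.available


class TestProcessTable:
    def _frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compound": ["ok", "leaky"],
                "C_d0": [2.0, 2.0],
                "C_d_t": [1.6, 1.6],
                "C_r_t": [0.2, 0.2],
                "t_min": [60.0, 60.0],
                "sucrose_frac": [0.01, 0.2],
            }
        )

    def test_qc_failures_are_excluded_not_estimated(self, geom):
        out = process_transwell_table(self._frame(), geom)
        ok = out[out["compound"] == "ok"].iloc[0]
        leaky = out[out["compound"] == "leaky"].iloc[0]
        assert ok["qc_pass"] and ok["R_ss"] == pytest.approx(0.36974, rel=1e-3)
        assert not leaky["qc_pass"] and math.isnan(leaky["R_ss"])

    def test_all_rows_failing_qc_is_an_error(self, geom):
        with pytest.raises(EstimationFailureError, match="0 rows"):
            process_transwell_table(self._frame(), geom, pe_threshold=0.0)
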
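"""Unit and property tests for the receptor-kinetics layer."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from androscape import (
    InfluxParams,
    KineticParams,
    KineticState,
    dissociation_constant,
    effective_ar_turnover,
    effective_km,
    kinetics_steady_state,
    simulate_kinetics,
    with_eta,
)
from androscape.errors import InvalidInputError, InvalidParameterError
from androscape.kinetics import (
    ar_production_rate,
    influx,
    kinetics_rhs,
    reductase_rate,
)


class TestDissociationConstant:
    def test_testosterone_value(self):
        assert dissociation_constant(0.14, 0.069) == pytest.approx(0.49286, abs=1e-4)
        assert round(dissociation_constant(0.14, 0.069), 2) == 0.49

    def test_dht_value(self):
        assert dissociation_constant(0.053, 0.018) == pytest.approx(0.33962, abs=1e-4)
        assert round(dissociation_constant(0.053, 0.018), 2) == 0.34

    def test_ratio_identity(self):
        assert dissociation_constant(1.0, 1.0) == 1.0

    def test_invalid_ka(self):
        with pytest.raises(InvalidParameterError):
            dissociation_constant(0.0, 0.1)
        with pytest.raises(InvalidParameterError):
            dissociation_constant(-1.0, 0.1)


class TestEffectiveKm:
    def test_no_inhibitor(self):
        assert effective_km(75.0, 0.0, 0.46) == 75.0

    def test_inhibitor_at_ki_doubles(self):
        assert effective_km(75.0, 0.46, 0.46) == pytest.approx(150.0)

    def test_tenfold(self):
        assert effective_km(75.0, 4.6, 0.46) == pytest.approx(825.0)

    def test_invalid_ki(self):
        with pytest.raises(InvalidParameterError):
            effective_km(75.0, 1.0, 0.0)


class TestReductaseRate:
    def test_no_substrate(self):
        assert reductase_rate(0.0, 5.0, 18.0, 75.0) == 0.0

    def test_half_vmax_at_km(self):
        assert reductase_rate(75.0, 5.0, 18.0, 75.0) == pytest.approx(45.0)

    def test_saturation(self):
        assert reductase_rate(1e12, 5.0, 18.0, 75.0) == pytest.approx(90.0, rel=1e-6)


class TestInflux:
    def test_zero_serum(self, kp):
        assert influx(0.0, kp.influx) == 0.0

    def test_half_saturation(self):
        p = InfluxParams(form="saturating", u_max=1.0, u_half=1.0)
        assert influx(1.0, p) == pytest.approx(0.5)

    def test_negative_serum_rejected(self, kp):
        with pytest.raises(InvalidInputError):
            influx(-1.0, kp.influx)

    def test_default_calibration_anchor(self, kp):
        # frozen defaults must put baseline total DHT in the normal range
        ss = kinetics_steady_state(kp, 5.0)
        assert 40.0 <= ss.total_DHT <= 60.0

    def test_tabulated_interpolation_and_flat_extrapolation(self):
        p = InfluxParams(form="tabulated", table=((1.0, 0.2), (3.0, 0.6), (5.0, 0.8)))
        assert influx(0.0, p) == 0.0
        assert influx(2.0, p) == pytest.approx(0.4)
        assert influx(50.0, p) == pytest.approx(0.8)  # flat beyond the table

    def test_tabulated_must_be_monotone(self):
        with pytest.raises(InvalidParameterError):
            InfluxParams(form="tabulated", table=((1.0, 0.5), (2.0, 0.3)))

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_saturating_monotone(self, a, b):
        p = InfluxParams(form="saturating", u_max=2.0, u_half=10.0)
        lo, hi = sorted((a, b))
        assert influx(lo, p) <= influx(hi, p)


class TestArProductionRate:
    def test_empty_pool(self):
        beta = math.log(2) / 3
        assert ar_production_rate(45.0, 0.0, 0.0, beta) == pytest.approx(45.0 * beta)

    def test_fully_bound_pool(self):
        assert ar_production_rate(45.0, 20.0, 25.0, 0.5) == 0.0

    def test_partial(self):
        beta = math.log(2) / 3
        assert ar_production_rate(45.0, 10.0, 30.0, beta) == pytest.approx(5.0 * beta)

    def test_clamped_at_zero(self):
        assert ar_production_rate(45.0, 40.0, 40.0, 0.5) == 0.0


class TestKineticsRhs:
    def test_all_zero_state(self, kp):
        s = KineticState(0.0, 0.0, 0.0, 0.0, 0.0)
        d = kinetics_rhs(s, kp, 5.0)
        u = influx(5.0, kp.influx)
        assert d[0] == pytest.approx(kp.beta_R_norm * kp.R_t)
        assert d[1] == pytest.approx(u)
        assert d[2] == d[3] == d[4] == 0.0

    def test_hand_evaluated_terms(self, kp):
        # independent term-by-term arithmetic for state (R=45, T=1, D=1, 0, 0)
        s = KineticState(45.0, 1.0, 1.0, 0.0, 0.0)
        u = kp.influx.u_max * 5.0 / (kp.influx.u_half + 5.0)
        v_red = 5.0 * 18.0 * 1.0 / (75.0 + 1.0)
        bind_T = 0.14 * 1.0 * 45.0
        bind_D = 0.053 * 1.0 * 45.0
        lam = kp.beta_R_norm * 45.0
        expected = np.array([
            lam - kp.beta_R * 45.0 - bind_T - bind_D,
            u - kp.beta_T * 1.0 - v_red - bind_T,
            v_red - kp.beta_D * 1.0 - bind_D,
            bind_T,
            bind_D,
        ])
        np.testing.assert_allclose(kinetics_rhs(s, kp, 5.0), expected, rtol=1e-12)

    @given(
        st.floats(0.0, 60.0), st.floats(0.0, 20.0), st.floats(0.0, 60.0),
        st.floats(0.0, 30.0), st.floats(0.0, 30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ar_pool_balance(self, R, T, D, ctr, cdr):
        # binding fluxes cancel: d(R + C_TR + C_DR)/dt == lambda - beta_R*R
        kp = KineticParams()
        s = KineticState(R, T, D, ctr, cdr)
        d = kinetics_rhs(s, kp, 5.0)
        lam = ar_production_rate(kp.R_t, ctr, cdr, kp.beta_R_norm)
        assert d[0] + d[3] + d[4] == pytest.approx(lam - kp.beta_R * R, abs=1e-9)


class TestSimulateKinetics:
    def test_androgen_free_converges_to_set_point(self, kp):
        traj = simulate_kinetics(kp, 0.0, 500.0)
        final = traj.final_state()
        assert final.R == pytest.approx(kp.R_t, abs=1e-6)
        for v in (final.T, final.D, final.C_TR, final.C_DR):
            assert v == pytest.approx(0.0, abs=1e-8)

    def test_transient_t_complex_peak(self, kp):
        traj = simulate_kinetics(kp, 5.0, 1000.0, n_out=2000)
        # T:AR peaks early, then DHT:AR overtakes and dominates at the end
        assert np.argmax(traj.C_TR) < np.argmax(traj.C_DR)
        assert traj.C_DR[-1] > traj.C_TR[-1]

    def test_total_ar_reaches_set_point(self, kp):
        traj = simulate_kinetics(kp, 5.0, 3000.0)
        assert traj.total_AR[-1] == pytest.approx(kp.R_t, abs=1e-5)

    def test_non_negativity(self, kp):
        traj = simulate_kinetics(kp, 5.0, 2000.0)
        assert np.all(traj.states >= 0.0)

    def test_invalid_horizon(self, kp):
        with pytest.raises(InvalidInputError):
            simulate_kinetics(kp, 5.0, 0.0)


class TestSteadyState:
    def test_androgen_free(self, kp):
        ss = kinetics_steady_state(kp, 0.0)
        assert ss.R == pytest.approx(kp.R_t, abs=1e-9)
        assert ss.T == ss.D == ss.C_TR == ss.C_DR == 0.0

    def test_baseline_binding_pattern(self, kp):
        # nearly all receptor is DHT-bound at physiologic serum T
        ss = kinetics_steady_state(kp, 5.0)
        assert ss.C_DR / kp.R_t > 0.8
        assert ss.C_DR > 5.0 * ss.C_TR
        assert ss.T < 1.0

    def test_matches_long_integration(self, kp):
        ss = kinetics_steady_state(kp, 5.0)
        endpoint = simulate_kinetics(kp, 5.0, 5000.0, n_out=2).final_state()
        np.testing.assert_allclose(ss.as_array(), endpoint.as_array(), atol=1e-6)

    def test_detailed_balance_residuals(self, kp):
        ss = kinetics_steady_state(kp, 5.0)
        assert abs(kp.ka_T * ss.T * ss.R - kp.kd_T * ss.C_TR) < 1e-9
        assert abs(kp.ka_D * ss.D * ss.R - kp.kd_D * ss.C_DR) < 1e-9

    def test_total_ar_equals_set_point(self, kp):
        for ts in (0.5, 2.0, 5.0, 10.0):
            ss = kinetics_steady_state(kp, ts)
            assert ss.total_AR == pytest.approx(kp.R_t, abs=1e-9)

    def test_saturation_in_serum_t(self, kp):
        ts_grid = [0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0]
        states = [kinetics_steady_state(kp, ts) for ts in ts_grid]
        bound = [s.C_TR + s.C_DR for s in states]
        assert all(b2 >= b1 for b1, b2 in zip(bound, bound[1:]))
        assert all(b <= kp.R_t for b in bound)
        free_d = [s.D for s in states]
        assert all(d2 > d1 for d1, d2 in zip(free_d, free_d[1:]))
        # bound complexes level off: relative gain shrinks
        assert (bound[-1] - bound[-2]) < 0.2 * (bound[1] - bound[0])

    def test_bound_androgen_linear_in_rt(self, kp):
        rts = [20.0, 40.0, 80.0]
        bound = [
            (lambda s: s.C_TR + s.C_DR)(kinetics_steady_state(replace(kp, R_t=rt), 5.0))
            for rt in rts
        ]
        # doubling R_t should roughly double bound androgen
        assert bound[1] / bound[0] == pytest.approx(2.0, rel=0.15)
        assert bound[2] / bound[1] == pytest.approx(2.0, rel=0.15)

    def test_inhibition_monotone(self, kp):
        totals = [
            kinetics_steady_state(with_eta(kp, eta), 5.0).total_DHT
            for eta in (1.0, 2.0, 5.0, 10.0, 50.0)
        ]
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_alpha_zero_blocks_dht(self, kp):
        ss = kinetics_steady_state(replace(kp, alpha=0.0), 5.0)
        assert ss.D == pytest.approx(0.0, abs=1e-12)
        assert ss.C_DR == pytest.approx(0.0, abs=1e-12)


class TestEffectiveArTurnover:
    def test_androgen_free_pool(self, kp):
        ss = kinetics_steady_state(kp, 0.0)
        assert effective_ar_turnover(ss, kp) == pytest.approx(kp.beta_R_norm)

    def test_fully_bound_pool(self, kp):
        ss = KineticState(0.0, 0.1, 0.1, 20.0, 25.0)
        assert effective_ar_turnover(ss, kp) == 0.0

    def test_monotone_decreasing_in_serum_t(self, kp):
        sweep = np.linspace(0.5, 10.0, 12)
        rates = [
            effective_ar_turnover(kinetics_steady_state(kp, ts), kp) for ts in sweep
        ]
        assert all(b < a for a, b in zip(rates, rates[1:]))


class TestValidation:
    def test_negative_state_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticState(-1.0, 0.0, 0.0, 0.0, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParams(kd_T=-0.1)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParams(K_M=0.0)

    def test_kd_properties(self, kp):
        assert kp.K_D_T == pytest.approx(0.069 / 0.14)
        assert kp.K_D_D == pytest.approx(0.018 / 0.053)
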
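"""Forward signal model tests: hand-derived values, limits, symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from qbold.models import (AcquisitionProtocol, BloodCompartment,
                          TissuePhysiology, apparent_dbv,
                          blood_signal_linear,
                          blood_signal_motional_narrowing,
                          blood_signal_powder, characteristic_frequency,
                          loglinear_predict, mean_square_field, oef_from_r2p,
                          static_dephasing_integral, tissue_signal_analytic,
                          tissue_signal_analytic_ase,
                          tissue_signal_asymptotic,
                          tissue_signal_asymptotic_r2p, total_signal_2c,
                          transition_time)


class TestCharacteristicFrequency:
    def test_hand_evaluated_product(self, proto):
        # (4/3)*pi*2.675e8*3*0.264e-6*0.40*0.40 = 141.98 rad/s
        phys = TissuePhysiology(oef=0.40, hct=0.40)
        assert characteristic_frequency(phys, proto) == pytest.approx(141.98,
                                                                      abs=0.05)

    def test_zero_oef_gives_zero(self, proto):
        assert characteristic_frequency(TissuePhysiology(oef=0.0),
                                        proto) == 0.0

    @given(oef=st.floats(0.01, 0.5))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_oef(self, oef):
        proto = AcquisitionProtocol()
        dw1 = characteristic_frequency(TissuePhysiology(oef=oef), proto)
        dw2 = characteristic_frequency(TissuePhysiology(oef=2 * oef), proto)
        assert dw2 == pytest.approx(2 * dw1, rel=1e-12)


class TestAnalyticTissueModel:
    def test_t_zero_is_one(self, phys, proto):
        assert tissue_signal_analytic(phys, proto, 0.0) == pytest.approx(1.0)

    def test_dbv_zero_reduces_to_spin_echo_decay(self, proto):
        phys = TissuePhysiology(oef=0.40, dbv=0.0)
        t = np.array([0.01, 0.03, 0.06])
        np.testing.assert_allclose(tissue_signal_analytic(phys, proto, t),
                                   np.exp(-phys.r2t * t), rtol=1e-10)

    def test_large_t_log_slope_approaches_r2t_plus_r2p(self, phys, proto):
        # d(-ln S)/dt -> R2t + DBV*dw in the long-time regime
        dw = characteristic_frequency(phys, proto)
        t = np.linspace(0.10, 0.11, 9)  # dw*t ~ 15: deep long-time regime
        ln_s = np.log(tissue_signal_analytic(phys, proto, t))
        slope = -np.gradient(ln_s, t).mean()
        assert slope == pytest.approx(phys.r2t + phys.dbv * dw, rel=0.01)

    def test_integral_asymptotes(self):
        assert static_dephasing_integral(0.05) == pytest.approx(
            0.3 * 0.05 ** 2, rel=5e-3)
        assert static_dephasing_integral(14.0) == pytest.approx(13.0,
                                                                rel=2e-3)

    def test_ase_mapping_even_in_tau(self, phys, proto):
        s_pos = tissue_signal_analytic_ase(phys, proto, 0.024)
        s_neg = tissue_signal_analytic_ase(phys, proto, -0.024)
        assert s_pos == pytest.approx(s_neg, rel=1e-12)


class TestAsymptoticTissueModel:
    def test_tau_zero_is_spin_echo_amplitude(self, phys, proto):
        expected = phys.s0 * np.exp(-phys.r2t * proto.te)
        assert tissue_signal_asymptotic(phys, proto, 0.0) == pytest.approx(
            expected, rel=1e-12)

    def test_parameterisations_agree(self, phys, proto):
        tau = proto.tau
        s_oef = tissue_signal_asymptotic(phys, proto, tau,
                                         parameterisation="OEF")
        s_r2p = tissue_signal_asymptotic(phys, proto, tau,
                                         parameterisation="R2p")
        np.testing.assert_allclose(s_oef, s_r2p, rtol=1e-14)

    def test_transition_time_hand_value(self, phys, proto):
        # kappa/dw = 1.76/141.98 = 12.4 ms
        assert transition_time(phys, proto, 1.76) == pytest.approx(12.4e-3,
                                                                   abs=0.1e-3)

    def test_zero_frequency_always_short_branch(self, proto):
        phys = TissuePhysiology(oef=0.0, dbv=0.05)
        s = tissue_signal_asymptotic(phys, proto, proto.tau)
        np.testing.assert_allclose(s, np.exp(-phys.r2t * proto.te),
                                   rtol=1e-12)

    def test_matches_long_branch_form_beyond_tc(self, phys, proto):
        dw = characteristic_frequency(phys, proto)
        r2p = phys.dbv * dw
        tau = 0.05
        expected = np.exp(-phys.r2t * proto.te) * np.exp(phys.dbv
                                                         - r2p * tau)
        assert tissue_signal_asymptotic(phys, proto, tau) == pytest.approx(
            expected, rel=1e-12)

    def test_even_in_tau(self, phys, proto):
        tau = np.array([-0.024, -0.008, 0.008, 0.024])
        s = tissue_signal_asymptotic(phys, proto, tau)
        np.testing.assert_allclose(s[:2], s[:1:-1], rtol=1e-12)

    def test_signal_bounded_by_s0(self, proto):
        for oef in (0.2, 0.45, 0.7):
            for dbv in (0.003, 0.05, 0.15):
                phys = TissuePhysiology(oef=oef, dbv=dbv)
                s = tissue_signal_asymptotic(phys, proto, proto.tau)
                assert np.all(s > 0) and np.all(s <= phys.s0)


class TestLogLinearPredict:
    def test_zero_parameters_return_log_spin_echo(self):
        tau = np.linspace(0.016, 0.064, 13)
        np.testing.assert_allclose(loglinear_predict(0.0, 0.0, 0.4, tau),
                                   np.log(0.4))

    def test_slope_is_minus_r2p(self):
        v1 = loglinear_predict(3.0, 0.05, 0.4, 0.020)
        v2 = loglinear_predict(3.0, 0.05, 0.4, 0.060)
        assert (v2 - v1) / 0.040 == pytest.approx(-3.0, rel=1e-12)

    def test_matches_long_branch_model_logs(self, phys, proto):
        dw = characteristic_frequency(phys, proto)
        r2p = phys.dbv * dw
        tau = proto.tau[proto.tau > 0.016]
        s = tissue_signal_asymptotic(phys, proto, tau)
        sse_t = phys.s0 * np.exp(-phys.r2t * proto.te)
        np.testing.assert_allclose(
            loglinear_predict(r2p, phys.dbv, sse_t, tau), np.log(s),
            rtol=1e-12)


class TestBloodModels:
    def test_linear_at_tau_zero(self, proto):
        from qbold.models import blood_relaxation_rates
        r2b, _ = blood_relaxation_rates(0.4, 0.4)
        assert blood_signal_linear(0.4, 0.4, proto, 0.0) == pytest.approx(
            np.exp(-r2b * proto.te), rel=1e-12)

    def test_linear_even_and_monotone(self, proto):
        assert blood_signal_linear(0.4, 0.4, proto, 0.03) == pytest.approx(
            blood_signal_linear(0.4, 0.4, proto, -0.03), rel=1e-12)
        tau = np.array([0.0, 0.01, 0.03, 0.06])
        s = blood_signal_linear(0.4, 0.4, proto, tau)
        assert np.all(np.diff(s) < 0)

    def test_powder_tau_zero_limit(self, proto):
        from qbold.models import blood_relaxation_rates
        r2b, _ = blood_relaxation_rates(0.4, 0.4)
        assert blood_signal_powder(0.4, 0.4, proto, 0.0) == pytest.approx(
            np.exp(-r2b * proto.te), rel=1e-9)

    def test_powder_magnitude_even(self, proto):
        assert blood_signal_powder(0.4, 0.4, proto, 0.02) == pytest.approx(
            blood_signal_powder(0.4, 0.4, proto, -0.02), rel=1e-12)

    def test_powder_against_fresnel_quadrature(self, proto):
        # brute-force the Fresnel integrals C, S at the eta implied by tau
        from qbold.models import blood_relaxation_rates
        tau = 0.032
        dw = characteristic_frequency(
            TissuePhysiology(oef=0.4, hct=0.4), proto)
        eta = np.sqrt(3.0 * dw * tau / np.pi)
        c_num = integrate.quad(lambda t: np.cos(np.pi * t * t / 2), 0,
                               eta)[0]
        s_num = integrate.quad(lambda t: np.sin(np.pi * t * t / 2), 0,
                               eta)[0]
        r2b, _ = blood_relaxation_rates(0.4, 0.4)
        expected = np.exp(-r2b * proto.te) * np.hypot(c_num, s_num) / eta
        assert blood_signal_powder(0.4, 0.4, proto, tau) == pytest.approx(
            expected, rel=1e-8)

    def test_mn_zero_oef_reduces_to_intrinsic_decay(self, blood, proto):
        s = blood_signal_motional_narrowing(0.0, 0.4, blood, proto, 0.02)
        assert s == pytest.approx(np.exp(-blood.r2b_true * proto.te),
                                  rel=1e-12)

    def test_mn_even_in_tau(self, blood, proto):
        sp = blood_signal_motional_narrowing(0.4, 0.4, blood, proto, 0.028)
        sm = blood_signal_motional_narrowing(0.4, 0.4, blood, proto, -0.028)
        assert sp == pytest.approx(sm, rel=1e-12)

    def test_mn_attenuation_below_one(self, blood, proto):
        s = blood_signal_motional_narrowing(0.4, 0.4, blood, proto,
                                            proto.tau)
        assert np.all(s <= np.exp(-blood.r2b_true * proto.te) + 1e-15)

    def test_mn_rejects_tau_beyond_te(self, blood, proto):
        with pytest.raises(ValueError):
            blood_signal_motional_narrowing(0.4, 0.4, blood, proto, 0.08)

    def test_g0_hand_evaluation(self):
        # (4/45)*0.4*0.6*(4*pi*3*0.4*0.264e-6)^2
        expected = (4.0 / 45.0) * 0.4 * 0.6 \
            * (4 * np.pi * 3.0 * 0.4 * 0.264e-6) ** 2
        assert mean_square_field(0.4, 0.4, 3.0) == pytest.approx(expected,
                                                                 rel=1e-12)


class TestTwoCompartment:
    def test_apparent_dbv_product(self):
        assert apparent_dbv(0.05, 0.5, 0.8) == pytest.approx(0.02)
        assert apparent_dbv(0.0, 0.5, 0.8) == 0.0
        assert apparent_dbv(0.05, 1.0, 1.0) == pytest.approx(0.05)

    def test_zeta_zero_reduces_to_tissue(self, phys, proto):
        blood0 = BloodCompartment(zeta_apparent=0.0)
        s2c = total_signal_2c(phys, blood0, proto, proto.tau)
        s1c = tissue_signal_asymptotic(phys, proto, proto.tau)
        np.testing.assert_allclose(s2c, s1c, rtol=1e-12)

    def test_zeta_one_reduces_to_blood(self, phys, proto):
        from qbold.models import blood_signal
        blood1 = BloodCompartment(zeta_apparent=1.0)
        s2c = total_signal_2c(phys, blood1, proto, proto.tau)
        sb = blood_signal(phys.oef, phys.hct, blood1, proto, proto.tau)
        np.testing.assert_allclose(s2c, phys.s0 * sb, rtol=1e-12)

    def test_midpoint_is_weighted_sum(self, phys, proto):
        from qbold.models import blood_signal
        blood = BloodCompartment(zeta_apparent=0.3)
        tau = 0.02
        st = tissue_signal_asymptotic(
            TissuePhysiology(oef=phys.oef, dbv=phys.dbv), proto, tau)
        sb = blood_signal(phys.oef, phys.hct, blood, proto, tau)
        expected = phys.s0 * (0.3 * sb + 0.7 * st)
        assert total_signal_2c(phys, blood, proto, tau) == pytest.approx(
            expected, rel=1e-12)


class TestOEFInversion:
    def test_round_trip(self, proto):
        phys = TissuePhysiology(oef=0.40, dbv=0.03)
        dw = characteristic_frequency(phys, proto)
        assert oef_from_r2p(dw * 0.03, 0.03, phys.hct,
                            proto) == pytest.approx(0.40, rel=1e-12)

    def test_hand_evaluation(self, proto):
        # 3*2.6 / (4*pi*gamma*B0*dchi0*0.40*0.036) ~ 0.20
        assert oef_from_r2p(2.6, 0.036, 0.40, proto) == pytest.approx(
            0.2035, abs=2e-3)

    def test_zero_r2p_gives_zero(self, proto):
        assert oef_from_r2p(0.0, 0.03, 0.40, proto) == 0.0

    def test_zero_dbv_is_missing_not_infinite(self, proto):
        out = oef_from_r2p(np.array([2.0, 2.0]), np.array([0.0, 0.03]),
                           0.40, proto)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestProtocolValidation:
    def test_tau_must_stay_below_te(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(te=0.05, tau_schedule=(0.0, 0.06))

    def test_tau_strictly_increasing(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(tau_schedule=(0.0, 0.0, 0.004))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            TissuePhysiology(oef=1.2)
        with pytest.raises(ValueError):
            TissuePhysiology(dbv=-0.01)
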
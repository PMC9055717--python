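"""Core QEPS function family: unit functions, components, landmarks, BMI."""
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from qepsgrowth.core import (
    DomainError,
    GrowthCurve,
    QEPSHeightParams,
    QEPSShape,
    QEPSWeightParams,
    age_at_p_fraction,
    age_at_peak_velocity,
    bmi_curve_value,
    bmi_to_conventional,
    curve_value,
    puberty_landmarks,
    unit_function,
    velocity,
)
from qepsgrowth import core

from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import random_height_params, random_shape


shape_strategy = st.builds(
    lambda kE, TQ, thetaP, bP, dS, bS: QEPSShape(
        kE=kE, TQ=TQ, thetaP=thetaP, bP=bP, thetaS=thetaP + dS, bS=bS),
    kE=st.floats(0.4, 3.0), TQ=st.floats(15.0, 24.0),
    thetaP=st.floats(8.0, 16.0), bP=st.floats(0.3, 2.0),
    dS=st.floats(0.6, 5.0), bS=st.floats(0.3, 2.0))

height_strategy = st.builds(
    QEPSHeightParams,
    hQ=st.floats(50.0, 120.0), hE=st.floats(30.0, 100.0),
    hP=st.floats(0.0, 40.0), shape=shape_strategy)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(params=height_strategy, age=st.floats(0.0, 28.0))
def test_additivity_and_bounds_property(params, age):
    """total = QES + P and 0 <= QES <= QE for arbitrary valid parameters."""
    total = curve_value(params, age, "total")
    qes = curve_value(params, age, "QES")
    p = curve_value(params, age, "P")
    qe = curve_value(params, age, "QE")
    assert total == pytest.approx(qes + p, rel=1e-9, abs=1e-9)
    assert -1e-9 <= qes <= qe + 1e-9


@settings(max_examples=60, derandomize=True, deadline=None)
@given(shape=shape_strategy, frac=st.floats(0.01, 0.99))
def test_p_fraction_inverse_property(shape, frac):
    """age_at_p_fraction is the exact inverse of the P unit function."""
    age = age_at_p_fraction(shape, frac)
    assume(age >= -shape.t0)   # tiny fractions of an early spurt may precede conception
    assert unit_function("P", age, shape) == pytest.approx(frac, abs=1e-9)


class TestUnitFunctions:
    def test_boundary_values(self, default_shape):
        sh = default_shape
        assert unit_function("E", -sh.t0, sh) == pytest.approx(0.0, abs=1e-12)
        assert unit_function("Q", sh.TQ - sh.t0, sh) == pytest.approx(1.0)
        assert unit_function("P", sh.thetaP, sh) == pytest.approx(0.5)
        assert unit_function("stop_sigma", sh.thetaS, sh) == pytest.approx(0.5)

    def test_range_and_monotonicity(self):
        rng = np.random.default_rng(1)
        t = np.linspace(-0.7, 28, 400)
        for _ in range(20):
            sh = random_shape(rng)
            for kind in ("Q", "E", "P", "stop_sigma"):
                v = unit_function(kind, t, sh)
                assert np.all((v >= 0) & (v <= 1))
                assert np.all(np.diff(v) >= -1e-12)
            # P strictly increasing away from float saturation of its tails
            p = unit_function("P", t, sh)
            interior = (p[:-1] > 1e-12) & (p[1:] < 1 - 1e-12)
            assert np.all(np.diff(p)[interior] > 0)
            after = t[t > sh.TQ - sh.t0]
            if after.size > 1:
                q = unit_function("Q", after, sh)
                assert np.allclose(q, 1.0)

    def test_age_before_conception_rejected(self, default_shape):
        with pytest.raises(DomainError):
            unit_function("E", -1.0, default_shape)

    def test_unknown_kind_rejected(self, default_shape):
        with pytest.raises(ValueError, match="unknown unit function"):
            unit_function("X", 1.0, default_shape)


class TestShapeInvariants:
    def test_stop_must_follow_pubertal_midpoint(self):
        with pytest.raises(ValueError, match="thetaS"):
            QEPSShape(kE=1.0, TQ=19, thetaP=14.0, bP=0.7, thetaS=13.0, bS=1.0)

    @pytest.mark.parametrize("field,value", [
        ("kE", -1.0), ("TQ", 0.0), ("bP", 6.0), ("bS", 5.0)])
    def test_invalid_fields_rejected(self, field, value):
        kw = dict(kE=1.0, TQ=19.0, thetaP=11.0, bP=0.7, thetaS=13.0, bS=1.0)
        kw[field] = value
        with pytest.raises(ValueError):
            QEPSShape(**kw)

    def test_negative_amplitude_rejected(self, default_shape):
        with pytest.raises(ValueError):
            QEPSHeightParams(hQ=-1.0, hE=60.0, hP=20.0, shape=default_shape)


class TestCurveValue:
    def test_additivity_identities(self):
        """total = QES + P = QE + P - S at random parameters and ages."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_height_params(rng)
            t = rng.uniform(-p.shape.t0 + 0.01, 28, size=20)
            total = curve_value(p, t, "total")
            qes = curve_value(p, t, "QES")
            pp = curve_value(p, t, "P")
            qe = curve_value(p, t, "QE")
            s = curve_value(p, t, "S")
            np.testing.assert_allclose(total, qes + pp, rtol=1e-9)
            np.testing.assert_allclose(total, qe + pp - s, rtol=1e-9)

    def test_qes_matches_quadrature_oracle(self):
        """QES equals the damped-basic-velocity integral (adaptive quad)."""
        sh = QEPSShape(kE=1.3, TQ=19.0, thetaP=11.7, bP=0.9, thetaS=13.7,
                       bS=1.2)
        p = QEPSHeightParams(hQ=80.0, hE=90.0, hP=18.0, shape=sh)

        def integrand(u):
            return (1 - core._sigma_s(u, sh)) * (
                80.0 * core._q_du(u, sh) + 90.0 * core._e_du(u, sh))

        for t in (5.0, 12.0, 16.0, 25.0):
            oracle, _ = quad(integrand, -sh.t0, t, limit=200)
            assert curve_value(p, t, "QES") == pytest.approx(oracle, abs=1e-6)
        # total at adult age = QES integral + attained P gain
        p_attained = 18.0 * core._p_u(25.0, sh)
        oracle, _ = quad(integrand, -sh.t0, 25.0, limit=200)
        assert curve_value(p, 25.0, "total") == pytest.approx(
            oracle + p_attained, abs=1e-6)

    def test_height_total_monotone(self):
        rng = np.random.default_rng(3)
        grid = np.arange(0.0, 25.0, 0.01)
        for _ in range(15):
            p = random_height_params(rng)
            h = curve_value(p, grid, "total")
            assert np.all(np.diff(h) >= -1e-10)

    def test_weight_scaled_by_whf(self, girl_weight_params):
        wp = girl_weight_params
        heavy = QEPSWeightParams(wQ=wp.wQ, wE=wp.wE, wP=wp.wP, shape=wp.shape,
                                 whf=0.1)
        t = np.linspace(0, 20, 30)
        np.testing.assert_allclose(curve_value(heavy, t), 1.1 * curve_value(wp, t))

    def test_unknown_component_rejected(self, girl_params):
        with pytest.raises(ValueError, match="component"):
            curve_value(girl_params, 10.0, "QP")


class TestVelocity:
    def test_q_plateau_velocity_zero(self, girl_params):
        sh = girl_params.shape
        assert velocity(girl_params, sh.TQ - sh.t0 + 0.5, "Q") == 0.0

    def test_component_velocities_sum(self, girl_params):
        t = np.linspace(0, 24, 49)
        v_tot = velocity(girl_params, t, "total")
        v = {c: velocity(girl_params, t, c) for c in ("QE", "P", "S")}
        np.testing.assert_allclose(v_tot, v["QE"] + v["P"] - v["S"], rtol=1e-9)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(11)
        h = 1e-4
        for _ in range(10):
            p = random_height_params(rng)
            for t in rng.uniform(0.5, 24, size=6):
                fd = (curve_value(p, t + h) - curve_value(p, t - h)) / (2 * h)
                v = velocity(p, t)
                assert v == pytest.approx(fd, abs=1e-4 * max(1.0, abs(v)))


class TestLandmarks:
    def test_age_at_p_fraction_closed_form(self):
        sh = QEPSShape(kE=1.3, TQ=19.0, thetaP=12.0, bP=0.9, thetaS=14.0,
                       bS=1.2)
        assert age_at_p_fraction(sh, 0.5) == pytest.approx(12.0)
        assert age_at_p_fraction(sh, 0.05) == pytest.approx(
            12.0 - 0.9 * np.log(19.0), abs=1e-9)
        assert age_at_p_fraction(sh, 0.05) == pytest.approx(9.350, abs=1e-3)

    def test_onset_has_five_percent_p_fraction(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            sh = random_shape(rng)
            a5 = age_at_p_fraction(sh, 0.05)
            assert unit_function("P", a5, sh) == pytest.approx(0.05, abs=1e-8)

    def test_closed_form_equals_bisection_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            sh = random_shape(rng)
            for frac in (0.05, 0.3, 0.8):
                root = brentq(lambda t: core._p_u(t, sh) - frac, -sh.t0, 30.0,
                              xtol=1e-10)
                assert age_at_p_fraction(sh, frac) == pytest.approx(
                    root, abs=1e-6)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_fraction_rejected(self, default_shape, frac):
        with pytest.raises(ValueError):
            age_at_p_fraction(default_shape, frac)

    def test_peak_velocity_near_midpoint_for_pure_spurt(self, default_shape):
        # negligible basic deceleration: peak of total velocity ~ thetaP
        p = QEPSHeightParams(hQ=0.0, hE=0.0, hP=20.0, shape=default_shape)
        assert age_at_peak_velocity(p) == pytest.approx(
            default_shape.thetaP, abs=1e-3)

    def test_peak_velocity_matches_grid_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = random_height_params(rng)
            a5 = age_at_p_fraction(p.shape, 0.05)
            grid = np.arange(a5 - 1.0, a5 + 6.0, 0.001)
            oracle = grid[np.argmax(velocity(p, grid, "total"))]
            assert age_at_peak_velocity(p) == pytest.approx(oracle, abs=2e-3)

    def test_no_spurt_flagged(self, default_shape):
        p = QEPSHeightParams(hQ=90.0, hE=60.0, hP=0.0, shape=default_shape)
        assert np.isnan(age_at_peak_velocity(p))
        lm = puberty_landmarks(p)
        assert not lm.has_spurt and np.isnan(lm.age_p5)

    def test_landmark_ordering(self, girl_params):
        lm = puberty_landmarks(girl_params)
        assert lm.age_p5 < lm.age_p50
        assert lm.age_p5 - 1 <= lm.age_tphv <= lm.age_p5 + 6


class TestBmi:
    def test_unit_identity(self, girl_params, girl_weight_params):
        # 25 kg at 1.00 m -> sqrt(25)/1.0 = 5 kg^0.5/m -> 25 kg/m^2
        t = brentq(lambda u: curve_value(girl_params, u) - 100.0, 0.0, 20.0)
        w_half = curve_value(girl_weight_params, t)
        b = bmi_curve_value(girl_params, girl_weight_params, t)
        assert b == pytest.approx(w_half / 1.0)
        assert bmi_to_conventional(b) == pytest.approx(b ** 2)
        assert bmi_to_conventional(4.2) == pytest.approx(17.64)

    def test_total_is_direct_ratio(self, girl_params, girl_weight_params):
        t = np.linspace(0.5, 22, 50)
        b = bmi_curve_value(girl_params, girl_weight_params, t)
        direct = (curve_value(girl_weight_params, t)
                  / (curve_value(girl_params, t) / 100.0))
        np.testing.assert_allclose(b, direct, rtol=1e-12)

    def test_p_component_is_total_minus_basic(self, girl_params,
                                              girl_weight_params):
        t = np.linspace(4, 20, 33)
        p = bmi_curve_value(girl_params, girl_weight_params, t, "P")
        tot = bmi_curve_value(girl_params, girl_weight_params, t, "total")
        basic = bmi_curve_value(girl_params, girl_weight_params, t, "QES")
        np.testing.assert_allclose(p, tot - basic, rtol=1e-12)

    def test_zero_height_rejected(self, default_shape, girl_weight_params):
        zero_h = QEPSHeightParams(hQ=0.0, hE=0.0, hP=0.0, shape=default_shape)
        with pytest.raises(ValueError, match="height"):
            bmi_curve_value(zero_h, girl_weight_params, 10.0)


class TestGrowthCurve:
    def test_kinds_dispatch(self, girl_params, girl_weight_params):
        t = np.array([6.0, 12.0])
        h = GrowthCurve("height", height_params=girl_params)
        w = GrowthCurve("sqrt_weight", weight_params=girl_weight_params)
        b = GrowthCurve("sqrt_bmi", height_params=girl_params,
                        weight_params=girl_weight_params)
        np.testing.assert_allclose(h.value(t), curve_value(girl_params, t))
        np.testing.assert_allclose(w.value(t), curve_value(girl_weight_params, t))
        np.testing.assert_allclose(
            b.value(t), bmi_curve_value(girl_params, girl_weight_params, t))

    def test_bmi_velocity_finite_difference(self, girl_params,
                                            girl_weight_params):
        b = GrowthCurve("sqrt_bmi", height_params=girl_params,
                        weight_params=girl_weight_params)
        t = 10.0
        v = b.velocity(t)
        h = 1e-3
        fd = (b.value(t + h) - b.value(t - h)) / (2 * h)
        assert v == pytest.approx(fd, rel=1e-3)

    def test_missing_params_rejected(self, girl_params):
        with pytest.raises(ValueError):
            GrowthCurve("sqrt_bmi", height_params=girl_params)
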
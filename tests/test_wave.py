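"""Planar-wave propulsion: integrals, wave counts, imputation, thrust and
speed prediction."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from microswim.fluid import WATER_25C
from microswim.records import OrganismRecord, Quantity
from microswim.spheroid import SpheroidBody, drag_correction_cfb, slender_drag_coeffs
from microswim.wave import (
    FlagellateGeometry,
    PlanarWave,
    WaveImputationError,
    impute_wave_parameter,
    net_thrust,
    predict_speed,
    wave_count,
    wave_integrals,
    wave_integrals_approx,
    wave_integrals_elliptic,
)


class TestWaveIntegrals:
    def test_straight_flagellum(self):
        assert wave_integrals(0.0) == (1.0, 0.0, 1.0)
        assert wave_integrals_approx(0.0) == (1.0, 0.0, 1.0)

    @pytest.mark.parametrize("a", [0.5, 1.0, 2.19, 2 * math.pi])
    def test_elliptic_closed_forms(self, a):
        """Quadrature matches the complete-elliptic-integral route:
        Λ = (2/π)√(1+a²)E(m), I1 = Λ − (2/π)K(m)/√(1+a²), m = a²/(1+a²)."""
        Lam, I1, I2 = wave_integrals(a)
        m = a * a / (1 + a * a)
        root = math.sqrt(1 + a * a)
        Lam_cf = (2 / math.pi) * root * special.ellipe(m)
        I1_cf = Lam_cf - (2 / math.pi) * special.ellipk(m) / root
        assert Lam == pytest.approx(Lam_cf, rel=1e-9)
        assert I1 == pytest.approx(I1_cf, rel=1e-9)
        assert I2 == pytest.approx(I1_cf + Lam_cf, rel=1e-9)
        assert wave_integrals_elliptic(a) == pytest.approx((Lam, I1, I2), rel=1e-9)

    def test_i1_reference_value(self):
        assert wave_integrals(2 * math.pi)[1] == pytest.approx(3.8630, abs=5e-4)

    def test_ranges_and_identity(self):
        for a in np.linspace(0.01, 2 * math.pi, 25):
            Lam, I1, I2 = wave_integrals(a)
            assert Lam >= 1.0
            assert 0.0 <= I1 < Lam  # thrust weight is below the arc weight
            assert I2 == pytest.approx(I1 + Lam, rel=1e-10)  # exact identity

    def test_quadrature_oracle_for_all_three(self):
        """Direct numerical period averages reproduce the returned values."""
        a = 1.7
        Lam, I1, I2 = wave_integrals(a)

        def avg(f):
            v, _ = integrate.quad(f, 0, 2 * math.pi, epsabs=1e-12, epsrel=1e-12)
            return v / (2 * math.pi)

        root = lambda al: math.sqrt(1 + (a * math.cos(al)) ** 2)
        assert Lam == pytest.approx(avg(root), rel=1e-9)
        assert I1 == pytest.approx(
            avg(lambda al: (a * math.cos(al)) ** 2 / root(al)), rel=1e-9
        )
        assert I2 == pytest.approx(
            avg(lambda al: (1 + 2 * (a * math.cos(al)) ** 2) / root(al)), rel=1e-9
        )


class TestApproximations:
    def test_thirteen_percent_bound(self):
        """The closed-form approximations stay within 13% of the exact
        integrals for all steepness values with h/λ < 1."""
        worst = 0.0
        for a in np.linspace(1e-3, 2 * math.pi, 400):
            exact = wave_integrals(a)
            approx = wave_integrals_approx(a)
            for ex, ap in zip(exact, approx):
                if ex > 0:
                    worst = max(worst, abs(ap - ex) / ex)
        assert worst <= 0.13
        assert worst > 0.115  # the bound is tight, not loose

    def test_worst_case_is_thrust_integral(self):
        """The largest error comes from the thrust integral I1, in the
        steep-wave regime (a ≈ 3.6), at about 12.6%."""
        grid = np.linspace(1e-3, 2 * math.pi, 800)
        errs = np.array(
            [
                [abs(ap - ex) / ex if ex > 0 else 0.0
                 for ex, ap in zip(wave_integrals(a), wave_integrals_approx(a))]
                for a in grid
            ]
        )
        i_row, i_col = np.unravel_index(errs.argmax(), errs.shape)
        assert i_col == 1  # I1
        assert 3.0 < grid[i_row] < 4.2
        assert errs[i_row, i_col] == pytest.approx(0.126, abs=2e-3)


class TestWaveCount:
    def test_zero_amplitude(self):
        assert wave_count(40, 24, 0.0) == pytest.approx(40 / 24)

    def test_reference_value(self):
        # a = 2π·4/24 ≈ 1.047, Λ ≈ 1.234 → n_w ≈ 1.35
        assert wave_integrals(2 * math.pi * 4 / 24)[0] == pytest.approx(1.234, abs=2e-3)
        assert wave_count(40, 24, 4) == pytest.approx(1.35, abs=0.005)

    def test_amplitude_imputation_roundtrip(self):
        n_w = wave_count(40, 24, 4)
        name, h = impute_wave_parameter(40, lam=24, h=None, n_w=n_w)
        assert name == "h" and h == pytest.approx(4.0, rel=1e-8)

    def test_wavelength_imputation_roundtrip(self):
        n_w = wave_count(40, 24, 4)
        name, lam = impute_wave_parameter(40, lam=None, h=4, n_w=n_w)
        assert name == "lam" and lam == pytest.approx(24.0, rel=1e-8)

    def test_zero_amplitude_branch(self):
        # n_w = L/λ exactly ⇒ the flagellum is straight
        name, h = impute_wave_parameter(40, lam=8, h=None, n_w=5)
        assert name == "h" and h == 0.0

    def test_infeasible_wave_count(self):
        # L/(n_w·λ) < 1 cannot be met by any amplitude (Λ ≥ 1)
        with pytest.raises(WaveImputationError):
            impute_wave_parameter(40, lam=24, h=None, n_w=5)


class TestNetThrust:
    def _setup(self):
        wave = PlanarWave(lam=24, h=4, f=35)
        geom = FlagellateGeometry(
            body=SpheroidBody(B=10, W=2), N=1, L=40, b=0.2
        )
        return wave, geom

    def test_positive_at_rest(self, water):
        wave, geom = self._setup()
        assert net_thrust(wave, geom, water, 0.0) > 0

    def test_zero_at_free_wave_speed(self, water):
        # no body: thrust vanishes at U = c·I1/I2
        wave, geom = self._setup()
        _, I1, I2 = wave_integrals(wave.steepness)
        U_free = wave.wave_speed * I1 / I2
        assert net_thrust(wave, geom, water, U_free) == pytest.approx(0.0, abs=1e-12)

    def test_against_line_integral_oracle(self, water):
        """Direct quadrature of the local force density over one wavelength
        (slender limit c⊥ = 2c∥) matches the period-averaged formula."""
        wave, geom = self._setup()
        U = 60.0
        _, c_par = slender_drag_coeffs(geom.L, geom.b, water)
        c = wave.wave_speed
        k = 2 * math.pi / wave.lam

        def dF(x):
            # local force balance: slope projections give 1/(1+A²), the arc
            # element contributes sqrt(1+A²), hence the 1/sqrt(1+A²) weight
            A = wave.h * k * math.cos(k * x)  # ∂y/∂x at t = 0
            y_t = c * A                        # ∂y/∂t for y = h sin(k(x+ct))
            c_perp = 2 * c_par
            return ((c_perp - c_par) * y_t * A - U * (c_par + c_perp * A * A)) / math.sqrt(
                1 + A * A
            )

        per_wavelength, _ = integrate.quad(dF, 0, wave.lam, epsabs=1e-12, epsrel=1e-12)
        n_w = wave_count(geom.L, wave.lam, wave.h)
        oracle = 1e-3 * n_w * per_wavelength  # mPa·µm² → pN
        assert net_thrust(wave, geom, water, U) == pytest.approx(oracle, rel=1e-8)

    def test_scales_with_flagella_count(self, water):
        wave, geom = self._setup()
        import dataclasses

        geom3 = dataclasses.replace(geom, N=3)
        assert net_thrust(wave, geom3, water, 10.0) == pytest.approx(
            3 * net_thrust(wave, geom, water, 10.0), rel=1e-12
        )


def _flagellate_record(**over):
    base = dict(
        species="model flagellate",
        group="flagellate",
        B=Quantity(point=10),
        W=Quantity(point=2),
        N=Quantity(point=1),
        L=Quantity(point=40),
        lam=Quantity(point=24),
        h=Quantity(point=4),
        f=Quantity(point=35),
    )
    base.update(over)
    return OrganismRecord(**base)


class TestPredictSpeed:
    def test_approx_reference_value(self, water):
        res = predict_speed(_flagellate_record(), mode="approx", fluid=water)
        assert res.value == pytest.approx(149.0, abs=1.0)

    def test_exact_and_approx_agree_within_error_budget(self, water):
        rec = _flagellate_record()
        exact = predict_speed(rec, "exact", water).value
        approx = predict_speed(rec, "approx", water).value
        assert approx == pytest.approx(exact, rel=0.25)

    def test_force_balance_residual(self, water):
        """The exact-mode speed satisfies thrust = body drag to 1e-8."""
        rec = _flagellate_record()
        res = predict_speed(rec, "exact", water)
        wave = PlanarWave(lam=24, h=4, f=35)
        geom = FlagellateGeometry(body=SpheroidBody(B=10, W=2), N=1, L=40, b=0.2)
        thrust = net_thrust(wave, geom, water, res.value)
        drag = 1e-3 * 3 * math.pi * water.eta * 10 * drag_correction_cfb(geom.body) * res.value
        assert thrust == pytest.approx(drag, rel=1e-8)

    def test_speed_below_wave_speed(self, water):
        for h in (1.0, 4.0, 8.0):
            res = predict_speed(_flagellate_record(h=Quantity(point=h)), "exact", water)
            assert 0 < res.value < 24 * 35

    def test_monotone_in_flagella_count_and_body_size(self, water):
        u1 = predict_speed(_flagellate_record(), "exact", water).value
        u4 = predict_speed(_flagellate_record(N=Quantity(point=4)), "exact", water).value
        assert u4 > u1
        big = predict_speed(
            _flagellate_record(B=Quantity(point=30), W=Quantity(point=6)), "exact", water
        ).value
        assert big < u1

    def test_body_free_limit(self, water):
        """Tiny body: U → c·I1/I2, and in approx mode →
        (2π²h²f/λ)/(1 + 4π²h²/λ²)."""
        rec = _flagellate_record(B=Quantity(point=1e-4), W=Quantity(point=1e-5))
        _, I1, I2 = wave_integrals(2 * math.pi * 4 / 24)
        assert predict_speed(rec, "exact", water).value == pytest.approx(
            24 * 35 * I1 / I2, rel=1e-3
        )
        lam, h, f = 24.0, 4.0, 35.0
        expected = (2 * math.pi**2 * h * h * f / lam) / (1 + 4 * math.pi**2 * h * h / lam**2)
        assert predict_speed(rec, "approx", water).value == pytest.approx(expected, rel=1e-3)

    def test_imputes_missing_width(self, water):
        res = predict_speed(_flagellate_record(W=None), "exact", water)
        assert any("aspect ratio" in s for s in res.imputations)
        manual = predict_speed(_flagellate_record(W=Quantity(point=6.0)), "exact", water)
        assert res.value == pytest.approx(manual.value)  # 0.60 × 10 µm

    def test_imputes_missing_wavelength(self, water):
        n_w = wave_count(40, 24, 4)
        rec = _flagellate_record(lam=None, n_w=Quantity(point=n_w))
        res = predict_speed(rec, "exact", water)
        full = predict_speed(_flagellate_record(), "exact", water)
        assert res.value == pytest.approx(full.value, rel=1e-6)
        assert any("wave-count" in s for s in res.imputations)

    def test_sperm_forces_single_flagellum(self, water):
        rec = _flagellate_record(group="spermatozoon", N=Quantity(point=7))
        res = predict_speed(rec, "exact", water)
        assert res.inputs["N"] == 1
        assert any("forced to 1" in s for s in res.imputations)

    def test_skips_without_wave_data(self, water):
        res = predict_speed(_flagellate_record(lam=None, h=None), "exact", water)
        assert not res.ok

    def test_infeasible_imputation_skips(self, water):
        rec = _flagellate_record(h=None, n_w=Quantity(point=5))
        res = predict_speed(rec, "exact", water)
        assert not res.ok and "imputation" in res.skip_reason
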
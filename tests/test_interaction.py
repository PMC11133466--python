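"""Relative velocity, detection regions, search rates, Arrhenius recovery
and velocity mismatch over the OTR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoforage import (
    CurveBand,
    ForagingPair,
    SearchRateCurve,
    VelocityCurve,
    detection_region_2d,
    detection_region_3d,
    fit_search_rate_arrhenius,
    mismatch_over_otr,
    relative_velocity,
    search_rate_active,
    search_rate_curve,
    search_rate_sessile,
)
from thermoforage.constants import BOLTZMANN_EV, celsius_to_kelvin
from thermoforage.interaction import DEFAULT_P_D_2D, DEFAULT_P_D_3D


class TestRelativeVelocity:
    def test_pythagorean_triple(self):
        assert relative_velocity(3.0, 4.0) == pytest.approx(5.0, rel=1e-12)

    def test_sessile_limit(self):
        assert relative_velocity(0.7, 0.0) == pytest.approx(0.7, rel=1e-12)

    def test_symmetry_and_sqrt2(self):
        assert relative_velocity(1.0, 1.0) == pytest.approx(np.sqrt(2), rel=1e-12)
        assert relative_velocity(2.0, 5.0) == relative_velocity(5.0, 2.0)

    @given(
        v_c=st.floats(0, 10, allow_nan=False),
        v_r=st.floats(0, 10, allow_nan=False),
    )
    def test_dominates_both_speeds(self, v_c, v_r):
        v = relative_velocity(v_c, v_r)
        assert v >= max(v_c, v_r) - 1e-12
        if min(v_c, v_r) > 1e-3 * max(v_c, v_r) > 0:
            assert v > max(v_c, v_r)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_velocity(-1.0, 2.0)


class TestDetectionRegions:
    def test_2d_unit_case(self):
        assert detection_region_2d(0.5, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_3d_unit_case(self):
        assert detection_region_3d(1 / np.pi, 1.0, 1.0) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_default_exponents(self):
        assert DEFAULT_P_D_2D == 0.21
        assert DEFAULT_P_D_3D == 0.2

    def test_2d_oracle(self):
        # independent power arithmetic: 2 * 0.01 * (1e-4 * 1e-6)**0.21
        assert detection_region_2d(0.01, 1e-4, 1e-6, 0.21) == pytest.approx(
            0.00015886564694485636, rel=1e-12
        )

    def test_3d_oracle(self):
        # pi * 0.01 * ((1e-4 * 1e-6)**0.2)**2
        assert detection_region_3d(0.01, 1e-4, 1e-6, 0.2) == pytest.approx(
            3.141592653589791e-06, rel=1e-12
        )

    def test_3d_d0_squared_variant(self):
        base = detection_region_3d(0.01, 1e-4, 1e-6, 0.2)
        squared = detection_region_3d(0.01, 1e-4, 1e-6, 0.2, d0_squared=True)
        assert squared == pytest.approx(base * 0.01, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detection_region_2d(0.01, -1.0, 1.0)
        with pytest.raises(ValueError):
            detection_region_3d(0.0, 1.0, 1.0)


ARGS = dict(v0_c=0.003, beta_c=0.75, E_c=0.7, m_c=3.8)


class TestSearchRates:
    def test_normalisation_at_tref(self):
        a = search_rate_sessile(**ARGS, T=288.15, Tref=288.15, D=0.005)
        assert a == pytest.approx(0.003 * 3.8**0.75 * 0.005, rel=1e-12)

    def test_sessile_frozen_oracle(self):
        a = search_rate_sessile(**ARGS, T=300.15, Tref=288.15, D=0.005)
        assert a == pytest.approx(0.00012601624027746736, rel=1e-12)

    def test_active_frozen_oracle(self):
        a = search_rate_active(
            **ARGS, v0_r=0.002, beta_r=0.6, E_r=0.65, m_r=0.5,
            T=300.15, Tref=288.15, D=0.005,
        )
        assert a == pytest.approx(0.00012740933441767518, rel=1e-12)

    def test_active_reduces_to_sessile_without_prey(self):
        sess = search_rate_sessile(**ARGS, T=305.0, Tref=288.15, D=0.01)
        act = search_rate_active(
            **ARGS, v0_r=0.0, beta_r=0.6, E_r=0.65, m_r=0.5,
            T=305.0, Tref=288.15, D=0.01,
        )
        assert act == pytest.approx(sess, rel=1e-12)

    def test_identical_parties_give_sqrt2(self):
        sess = search_rate_sessile(**ARGS, T=295.0, Tref=288.15, D=0.01)
        act = search_rate_active(
            v0_c=0.003, beta_c=0.75, E_c=0.7, m_c=3.8,
            v0_r=0.003, beta_r=0.75, E_r=0.7, m_r=3.8,
            T=295.0, Tref=288.15, D=0.01,
        )
        assert act == pytest.approx(np.sqrt(2) * sess, rel=1e-12)

    def test_active_at_least_sessile(self):
        T = np.linspace(280, 320, 30)
        sess = search_rate_sessile(**ARGS, T=T, Tref=288.15, D=0.01)
        act = search_rate_active(
            **ARGS, v0_r=0.001, beta_r=0.6, E_r=0.65, m_r=0.5,
            T=T, Tref=288.15, D=0.01,
        )
        assert np.all(act >= sess)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            search_rate_sessile(**ARGS, T=-5.0, Tref=288.15, D=0.01)


def _pair(strategy="sessile", dim=2):
    return ForagingPair(
        consumer="pred", resource="prey", strategy=strategy, dimensionality=dim,
        m_c=3.8e-6, m_r=0.5e-6,
    )


def make_curve(temps, est, lo=None, hi=None, tref=288.15):
    est = np.asarray(est, dtype=float)
    band = CurveBand(
        temps=temps,
        estimate=est,
        lower=est if lo is None else np.asarray(lo, float),
        upper=est if hi is None else np.asarray(hi, float),
    )
    return SearchRateCurve(pair=_pair(), site="s", band=band, Tref=tref)


class TestArrheniusFit:
    def test_exact_recovery_from_sessile_curve(self):
        temps = np.arange(10.0, 30.0, 1.0)
        T = celsius_to_kelvin(temps)
        tref = 288.15
        a = search_rate_sessile(**ARGS, T=T, Tref=tref, D=0.01)
        summ = fit_search_rate_arrhenius(make_curve(temps, a, tref=tref))
        assert summ.E == pytest.approx(0.7, rel=1e-9)
        assert np.exp(summ.lnB0) == pytest.approx(
            0.003 * 3.8**0.75 * 0.01, rel=1e-9
        )
        assert summ.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_zero_sensitivity(self):
        temps = np.arange(10.0, 20.0, 1.0)
        summ = fit_search_rate_arrhenius(make_curve(temps, np.full(10, 0.02)))
        assert summ.E == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_ols_oracle(self):
        rng = np.random.default_rng(5)
        temps = np.arange(10.0, 26.0, 1.0)
        T = celsius_to_kelvin(temps)
        tref = 288.15
        a = 0.01 * np.exp(-0.9 / BOLTZMANN_EV * (1 / T - 1 / tref))
        a *= rng.lognormal(0, 0.05, a.size)
        summ = fit_search_rate_arrhenius(
            make_curve(temps, a, tref=tref), temp_range=(10.0, 25.0)
        )
        x = -(1 / (BOLTZMANN_EV * T) - 1 / (BOLTZMANN_EV * tref))
        slope = np.sum((x - x.mean()) * (np.log(a) - np.log(a).mean())) / np.sum(
            (x - x.mean()) ** 2
        )
        assert summ.E == pytest.approx(slope, rel=1e-9)

    def test_nonpositive_rate_rejected(self):
        temps = np.arange(10.0, 20.0, 1.0)
        vals = np.linspace(0.0, 0.01, 10)
        with pytest.raises(ValueError):
            fit_search_rate_arrhenius(
                make_curve(temps, vals), temp_range=(10.0, 19.0)
            )


def velocity_curve(temps, est, lo=None, hi=None, **kw):
    est = np.asarray(est, dtype=float)
    band = CurveBand(
        temps=temps,
        estimate=est,
        lower=est if lo is None else np.asarray(lo, float),
        upper=est if hi is None else np.asarray(hi, float),
    )
    defaults = dict(
        taxon="t", site="s", v0=0.003, beta=0.75, E=0.7, Tref=288.15,
        mass_mg=1.0, mass_kg=1e-6,
    )
    defaults.update(kw)
    return VelocityCurve(band=band, **defaults)


class TestMismatch:
    temps = np.arange(10.0, 30.5, 0.5)

    def test_identical_curves(self):
        v = 0.01 + 0.001 * (self.temps - 10)
        a = velocity_curve(self.temps, v, lo=v - 0.001, hi=v + 0.001)
        b = velocity_curve(self.temps, v, lo=v - 0.001, hi=v + 0.001)
        mm = mismatch_over_otr(a, b, (12.0, 25.0))
        assert mm["mean_delta_v"] == pytest.approx(0.0, abs=1e-15)
        assert mm["band_non_overlap_fraction"] == 0.0

    def test_constant_offset_with_disjoint_bands(self):
        v = 0.01 + 0.001 * (self.temps - 10)
        c = 0.05
        prey = velocity_curve(self.temps, v, lo=v - 0.001, hi=v + 0.001)
        pred = velocity_curve(
            self.temps, v + c, lo=v + c - 0.001, hi=v + c + 0.001
        )
        mm = mismatch_over_otr(pred, prey, (12.0, 25.0))
        assert mm["mean_delta_v"] == pytest.approx(c, rel=1e-9)
        assert mm["band_non_overlap_fraction"] == 1.0
        assert mm["sign_consistency"] == 1.0

    def test_mean_delta_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        va = 0.01 + 0.002 * rng.random(self.temps.size)
        vb = 0.01 + 0.002 * rng.random(self.temps.size)
        pred = velocity_curve(self.temps, va)
        prey = velocity_curve(self.temps, vb)
        otr, step = (11.0, 27.0), 0.1
        mm = mismatch_over_otr(pred, prey, otr, grid_step=step)
        grid = np.arange(otr[0], otr[1] + step / 2, step)
        expected = np.mean(
            np.interp(grid, self.temps, va) - np.interp(grid, self.temps, vb)
        )
        assert mm["mean_delta_v"] == pytest.approx(expected, rel=1e-9)

    def test_otr_outside_grid_rejected(self):
        a = velocity_curve(self.temps, np.full(self.temps.size, 0.01))
        with pytest.raises(ValueError):
            mismatch_over_otr(a, a, (5.0, 20.0))


class TestSearchRateCurve:
    temps = np.arange(10.0, 40.5, 0.5)

    def _vc(self, v0, beta, E, mass_mg, reps=None):
        T = celsius_to_kelvin(self.temps)
        est = v0 * mass_mg**beta * np.exp(
            -E / BOLTZMANN_EV * (1 / T - 1 / 288.15)
        )
        vc = velocity_curve(
            self.temps, est, v0=v0, beta=beta, E=E, mass_mg=mass_mg,
            mass_kg=mass_mg * 1e-6,
        )
        if reps is not None:
            vc.replicates = np.asarray(reps, dtype=float)
        return vc

    def test_sessile_ignores_prey_parameters(self):
        pair = _pair("sessile", 2)
        cons = self._vc(0.003, 0.75, 0.7, 3.8)
        prey_a = self._vc(0.002, 0.6, 0.65, 0.5)
        prey_b = self._vc(0.009, 0.9, 1.5, 2.5)
        a = search_rate_curve(pair, cons, prey_a)
        b = search_rate_curve(pair, cons, prey_b)
        np.testing.assert_allclose(a.band.estimate, b.band.estimate)

    def test_monotone_rising_portion(self):
        pair = _pair("active", 3)
        cons = self._vc(0.003, 0.75, 0.7, 3.8)
        prey = self._vc(0.002, 0.6, 0.65, 0.5)
        sr = search_rate_curve(pair, cons, prey)
        assert np.all(np.diff(sr.band.estimate) > 0)

    def test_pointwise_composition_oracle(self):
        pair = _pair("active", 3)
        cons = self._vc(0.003, 0.75, 0.7, 3.8)
        prey = self._vc(0.002, 0.6, 0.65, 0.5)
        sr = search_rate_curve(pair, cons, prey)
        D = detection_region_3d(pair.d0, pair.m_c, pair.m_r, pair.p_d)
        i = 17
        T = celsius_to_kelvin(self.temps[i])
        expected = search_rate_active(
            0.003, 0.75, 0.7, 3.8, 0.002, 0.6, 0.65, 0.5, T, 288.15, D
        )
        assert sr.band.estimate[i] == pytest.approx(expected, rel=1e-12)

    def test_replicates_paired_by_index(self):
        pair = _pair("active", 3)
        reps_c = [[0.003, 0.75, 0.7], [0.004, 0.75, 0.8]]
        reps_r = [[0.002, 0.6, 0.65], [0.001, 0.6, 0.6]]
        cons = self._vc(0.003, 0.75, 0.7, 3.8, reps=reps_c)
        prey = self._vc(0.002, 0.6, 0.65, 0.5, reps=reps_r)
        sr = search_rate_curve(pair, cons, prey)
        D = detection_region_3d(pair.d0, pair.m_c, pair.m_r, pair.p_d)
        T = celsius_to_kelvin(self.temps)
        curves = np.array(
            [
                search_rate_active(
                    *reps_c[i], 3.8, *reps_r[i], 0.5, T, 288.15, D
                )
                for i in range(2)
            ]
        )
        lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
        np.testing.assert_allclose(sr.band.lower, lo, rtol=1e-12)
        np.testing.assert_allclose(sr.band.upper, hi, rtol=1e-12)

    def test_active_requires_prey(self):
        pair = _pair("active", 3)
        cons = self._vc(0.003, 0.75, 0.7, 3.8)
        with pytest.raises(ValueError):
            search_rate_curve(pair, cons, None)

    def test_default_p_d_by_dimensionality(self):
        assert _pair("sessile", 2).p_d == 0.21
        assert _pair("active", 3).p_d == 0.2
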
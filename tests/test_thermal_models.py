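"""Closed-form identities and threshold extraction for every curve family."""

import math

import numpy as np
import pytest

from phenotherm import thermal_models as tm


class TestLinear:
    @pytest.mark.parametrize("a,b,T,expected", [
        (-0.02, 0.002, 10.0, 0.0),      # the line's root, Tmin
        (-0.077, 0.005, 30.0, 0.073),   # published egg coefficients
        (-0.02, 0.002, 35.0, 0.05),
    ])
    def test_eval(self, a, b, T, expected):
        assert tm.eval_linear(tm.LinearDDParams(a, b), T) == pytest.approx(
            expected, abs=1e-12)

    def test_clipping_below_threshold(self):
        p = tm.LinearDDParams(-0.02, 0.002)
        assert tm.eval_linear(p, 5.0) == 0.0
        assert tm.eval_linear(p, 5.0, clip=False) == pytest.approx(-0.01)

    def test_thresholds(self):
        thr = tm.thresholds_from_model(tm.LinearDDParams(-0.02, 0.002))
        assert thr.Tmin == pytest.approx(10.0)
        assert thr.K == pytest.approx(500.0)
        # the extracted threshold is the exact root of the line
        assert tm.eval_linear(tm.LinearDDParams(-0.02, 0.002), thr.Tmin) == 0.0

    def test_zero_slope_undefined(self):
        with pytest.raises(tm.ThresholdUndefinedError):
            tm.thresholds_from_model(tm.LinearDDParams(0.01, 0.0))


class TestLogan1:
    EGG = tm.Logan1Params(Y=0.002, p=0.199, Tmax=39.537, v=4.700)

    def test_zero_at_tmax(self):
        p = tm.Logan1Params(Y=0.1, p=0.15, Tmax=38.0, v=3.0)
        assert tm.eval_logan1(p, 38.0) == pytest.approx(0.0, abs=1e-15)

    def test_zero_scale(self):
        p = tm.Logan1Params(Y=0.0, p=0.15, Tmax=38.0, v=3.0)
        assert np.all(tm.eval_logan1(p, np.linspace(0, 45, 20)) == 0.0)

    def test_egg_curve_matches_direct_formula(self):
        # independent evaluation of the closed form, written out longhand
        T = 35.0
        expected = 0.002 * (math.exp(0.199 * T)
                            - math.exp(0.199 * 39.537 - (39.537 - T) / 4.700))
        assert tm.eval_logan1(self.EGG, T) == pytest.approx(expected, rel=1e-14)

    def test_thresholds(self):
        thr = tm.thresholds_from_model(self.EGG)
        assert thr.Tmax == pytest.approx(39.537)
        assert thr.Tmin is None  # rate positive all the way down to 0 degC
        # the optimum maximises the curve
        grid = np.arange(0.0, 39.537, 0.001)
        best = grid[np.argmax(tm.eval_logan1(self.EGG, grid))]
        assert thr.Topt == pytest.approx(best, abs=0.01)


class TestAllahyari:
    NYMPH = tm.AllahyariParams(P=1.846, Tmin=13.081, Tmax=43.468, n=2.593,
                               m=0.073)

    def test_zero_at_both_limits(self):
        assert tm.eval_allahyari(self.NYMPH, self.NYMPH.Tmin) == 0.0
        assert tm.eval_allahyari(self.NYMPH, self.NYMPH.Tmax) == 0.0

    def test_zero_outside_domain(self):
        assert tm.eval_allahyari(self.NYMPH, 5.0) == 0.0
        assert tm.eval_allahyari(self.NYMPH, 50.0) == 0.0

    def test_topt_matches_closed_form(self):
        # argmax of x^n (1 - x^m) is x* = (n/(n+m))^(1/m)
        p = self.NYMPH
        xstar = (p.n / (p.n + p.m)) ** (1.0 / p.m)
        topt_closed = p.Tmin + xstar * (p.Tmax - p.Tmin)
        thr = tm.thresholds_from_model(p)
        assert thr.Topt == pytest.approx(topt_closed, abs=0.01)
        # and agrees with a fine grid scan
        grid = np.arange(p.Tmin, p.Tmax, 0.001)
        best = grid[np.argmax(tm.eval_allahyari(p, grid))]
        assert thr.Topt == pytest.approx(best, abs=0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            tm.AllahyariParams(P=1.0, Tmin=30.0, Tmax=20.0, n=2.0, m=0.1)


class TestWangMortality:
    def test_symmetric_minimum_at_topt(self):
        p = tm.WangMortalityParams(variant="symmetric", Topt=30.0, B=2.5,
                                   H=0.004)
        assert tm.eval_wang_mortality(p, 30.0) == pytest.approx(
            1.0 - math.exp(-4.0 * p.H), rel=1e-14)

    def test_symmetric_symmetry(self):
        p = tm.WangMortalityParams(variant="symmetric", Topt=28.0, B=3.0,
                                   H=0.02)
        for d in (0.5, 2.0, 7.5, 15.0):
            assert tm.eval_wang_mortality(p, 28.0 + d) == pytest.approx(
                tm.eval_wang_mortality(p, 28.0 - d), rel=1e-12)

    def test_two_sided_limits_and_formula(self):
        p = tm.WangMortalityParams(variant="two_sided", Tl=15.0, Th=40.0,
                                   B=2.0, H=0.05)
        assert tm.eval_wang_mortality(p, -60.0) == pytest.approx(1.0)
        T = 27.5
        expected = 1.0 - math.exp(
            -0.05 * (1.0 + math.exp(-(T - 15.0) / 2.0))
            * (1.0 + math.exp(-(40.0 - T) / 2.0)))
        assert tm.eval_wang_mortality(p, T) == pytest.approx(expected, rel=1e-14)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            p = tm.WangMortalityParams(
                variant="two_sided",
                Tl=rng.uniform(0, 20), Th=rng.uniform(25, 50),
                B=rng.uniform(0.2, 5), H=rng.uniform(1e-4, 0.5))
            m = tm.eval_wang_mortality(p, rng.uniform(-50, 80, 50))
            assert np.all((m >= 0.0) & (m <= 1.0))


class TestWang7:
    def test_fmax_at_topt(self):
        p = tm.Wang7Params(Fmax=3416.0, Topt=30.0, B1=2.3, Bh=1.7)
        assert tm.eval_wang7_fecundity(p, 30.0) == pytest.approx(3416.0)

    def test_symmetric_widths_give_symmetric_curve(self):
        p = tm.Wang7Params(Fmax=1000.0, Topt=27.0, B1=2.0, Bh=2.0)
        for d in (1.0, 3.0, 6.0):
            assert tm.eval_wang7_fecundity(p, 27.0 + d) == pytest.approx(
                tm.eval_wang7_fecundity(p, 27.0 - d), rel=1e-12)

    def test_reference_optimum_near_30(self, ref_model):
        # the fitted fecundity curve peaks at the 30 degC rearing optimum
        grid = np.arange(15.0, 40.0 + 1e-9, 1.0)
        vals = tm.eval_wang7_fecundity(ref_model.fecundity, grid)
        assert abs(grid[np.argmax(vals)] - 30.0) <= 1.0
        assert tm.eval_wang7_fecundity(ref_model.fecundity, 30.0) == \
            pytest.approx(ref_model.fecundity.Fmax)

    def test_vanishes_far_from_topt(self):
        p = tm.Wang7Params(Fmax=1000.0, Topt=30.0, B1=2.0, Bh=2.0)
        assert tm.eval_wang7_fecundity(p, -20.0) < 1e-6
        assert tm.eval_wang7_fecundity(p, 80.0) < 1e-6


class TestOvipositionCDF:
    def test_zero_at_zero(self):
        p = tm.OvipositionCDFParams(a=0.3, b=1.7, c=0.3)
        assert tm.eval_oviposition_cdf(p, 0.0) == 0.0

    def test_saturates_to_one(self):
        p = tm.OvipositionCDFParams(a=1.0, b=0.5, c=0.2)
        assert tm.eval_oviposition_cdf(p, 50.0) == pytest.approx(1.0)

    def test_closed_form_half_point(self):
        p = tm.OvipositionCDFParams(a=1.0, b=0.0, c=0.0)
        assert tm.eval_oviposition_cdf(p, math.log(2.0)) == pytest.approx(0.5)

    def test_decreasing_cdf_rejected(self):
        with pytest.raises(ValueError):
            tm.OvipositionCDFParams(a=0.5, b=0.0, c=-1.0)

    def test_negative_age_rejected(self):
        p = tm.OvipositionCDFParams(a=0.3, b=1.7, c=0.3)
        with pytest.raises(ValueError):
            tm.eval_oviposition_cdf(p, -0.5)


class TestSenescence:
    def test_exp_simple_flat(self):
        p = tm.ExpSimpleParams(b1=0.01, b2=0.0)
        assert np.all(tm.eval_senescence(p, np.linspace(0, 40, 9)) == 0.01)

    def test_exp_simple_monotone_on_male_longevity(self):
        # a curve fit to decreasing adult longevities must give a rate
        # that increases with temperature
        from phenotherm import datasets
        params = datasets.reference_params()["senescence_male"]
        T = np.array([20.0, 23.0, 25.0, 30.0, 35.0, 37.0])
        s = tm.eval_senescence(params, T)
        assert np.all(np.diff(s) > 0)

    def test_hilbert_logan3_at_tmin(self):
        p = tm.HilbertLogan3Params(trid=0.1, Tmin=10.0, Tmax=30.0, D=50.0,
                                   Dt=4.0)
        raw = tm.eval_senescence(p, 10.0, clip=False)
        assert raw == pytest.approx(-0.1 * math.exp(-30.0 / 4.0), rel=1e-12)
        assert tm.eval_senescence(p, 10.0) == 0.0


def test_oracle_agreement(rng):
    """All evaluators agree with independently coded formulas on random draws."""
    def oracle_logan1(Y, p, Tmax, v, T):
        return Y * (math.exp(p * T) - math.exp(p * Tmax - (Tmax - T) / v))

    def oracle_allahyari(P, Tmin, Tmax, n, m, T):
        x = (T - Tmin) / (Tmax - Tmin)
        if x < 0 or x > 1:
            return 0.0
        return P * x**n * (1 - x**m)

    def oracle_wang(Tlo, Thi, B, H, T):
        return 1.0 - math.exp(-H * (1 + math.exp(-(T - Tlo) / B))
                              * (1 + math.exp(-(Thi - T) / B)))

    for _ in range(1000):
        T = float(rng.uniform(0, 45))
        pl = tm.Logan1Params(Y=rng.uniform(1e-4, 0.1), p=rng.uniform(0.05, 0.3),
                             Tmax=rng.uniform(35, 45), v=rng.uniform(1, 8))
        got = tm.eval_logan1(pl, T, clip=False)
        want = oracle_logan1(pl.Y, pl.p, pl.Tmax, pl.v, T)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

        pa = tm.AllahyariParams(P=rng.uniform(0.1, 20), Tmin=rng.uniform(5, 18),
                                Tmax=rng.uniform(38, 46), n=rng.uniform(0.5, 6),
                                m=rng.uniform(0.02, 2))
        got = tm.eval_allahyari(pa, T)
        want = max(oracle_allahyari(pa.P, pa.Tmin, pa.Tmax, pa.n, pa.m, T), 0.0)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

        pw = tm.WangMortalityParams(variant="two_sided",
                                    Tl=rng.uniform(5, 18),
                                    Th=rng.uniform(30, 45),
                                    B=rng.uniform(0.3, 5),
                                    H=rng.uniform(1e-3, 0.3))
        got = tm.eval_wang_mortality(pw, T)
        want = oracle_wang(pw.Tl, pw.Th, pw.B, pw.H, T)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-15)


class TestSerialization:
    def test_round_trip_each_family(self, ref_params):
        for key, params in ref_params.items():
            rebuilt = tm.params_from_dict(tm.params_to_dict(params))
            assert rebuilt == params, key

    def test_bundle_round_trip(self, tmp_path, ref_params):
        path = tmp_path / "bundle.json"
        tm.save_param_bundle(ref_params, path)
        assert tm.load_param_bundle(path) == ref_params

    def test_unknown_schema_version_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 999, "models": {}}')
        with pytest.raises(ValueError, match="schema version"):
            tm.load_param_bundle(path)
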
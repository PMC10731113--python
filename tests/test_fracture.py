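"""J-integral machinery: geometry factor, K, J components, segmentation,
plastic areas and R-curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from bonequal import DomainError, ValidationError
from bonequal.config import FractureConfig
from bonequal.core_io import BendTestRecord, CrackLengthTable
from bonequal.fracture import (SegmentedRecord, build_r_curve, elastic_j,
                               fit_r_curve, geometry_factor, plastic_area,
                               plastic_j, segment_record, stress_intensity)

# independent symbolic evaluations of the SENB geometry-factor expression
# (frozen from an exact rational sympy computation)
F_ORACLE = {0.3: 1.52124562219, 0.45: 2.28547375438,
            0.5: 2.66250000000, 0.6: 3.77160183145}


class TestGeometryFactor:
    def test_against_symbolic_oracle(self):
        for x, expected in F_ORACLE.items():
            assert geometry_factor(x) == pytest.approx(expected, rel=1e-9)

    def test_limits(self):
        assert geometry_factor(1e-10) < 1e-4          # sqrt(a/W) prefactor
        assert geometry_factor(1 - 1e-10) > 1e10      # (1-a/W)^{-3/2} blowup

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, x):
        with pytest.raises(DomainError):
            geometry_factor(x)

    @given(st.floats(min_value=0.2, max_value=0.799))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, x):
        assert geometry_factor(x + 1e-3) > geometry_factor(x)


class TestStressIntensityAndJ:
    def test_zero_load(self, geom):
        assert stress_intensity(0.0, geom, 1.5) == 0.0

    def test_hand_oracle(self, geom, mat):
        # P = 15 N, S = 10 mm, B = 2 mm, W = 3 mm, a = 1.5 mm (exact arithmetic)
        k = stress_intensity(15.0, geom, 1.5)
        assert k == pytest.approx(1215259.42446, rel=1e-9)
        assert elastic_j(k, mat) == pytest.approx(68.9199218750, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=1.5, max_value=8.0))
    @settings(max_examples=30, derandomize=True)
    def test_homogeneity(self, p, scale):
        """K is degree-1 and J_el degree-2 homogeneous in the load."""
        from bonequal import MaterialConstants, SpecimenGeometry
        geom = SpecimenGeometry(B=2.0, W=3.0, L=12.0, S=10.0, a0=1.5)
        mat = MaterialConstants(E=19.5, nu=0.3)
        k1 = stress_intensity(p, geom, 1.5)
        k2 = stress_intensity(scale * p, geom, 1.5)
        assert k2 == pytest.approx(scale * k1, rel=1e-12)
        assert elastic_j(k2, mat) == pytest.approx(scale**2 * elastic_j(k1, mat),
                                                   rel=1e-12)

    def test_domain_errors(self, geom, mat):
        with pytest.raises(DomainError):
            stress_intensity(1.0, geom, 3.0)
        with pytest.raises(DomainError):
            stress_intensity(-1.0, geom, 1.5)
        with pytest.raises(DomainError):
            elastic_j(-1.0, mat)

    def test_plastic_j_unit_oracle(self, geom):
        # A_pl = 1 mJ, B = 2 mm, W - a = 1.5 mm -> 2e-3 / 3e-6 = 666.67 J/m^2
        assert plastic_j(1e-3, geom, 1.5) == pytest.approx(2000.0 / 3.0, rel=1e-12)
        # halving the ligament doubles J_pl
        assert plastic_j(1e-3, geom, 2.25) == pytest.approx(2 * 2000.0 / 3.0,
                                                            rel=1e-12)
        with pytest.raises(DomainError):
            plastic_j(1e-3, geom, 3.0)


def _linear_ramp(n=100, slope=1.5, rate=0.2):
    d = np.arange(n) * rate
    return BendTestRecord(np.arange(1.0, n + 1), slope * d, d)


class TestSegmentation:
    def test_linear_ramp_single_loading_segment(self):
        seg = segment_record(_linear_ramp(), FractureConfig())
        kinds = [k for k, _, _ in seg.segments]
        assert kinds.count("loading") == 1 and "unloading" not in kinds
        assert len(seg.trigger_index) == 0
        assert seg.loading_slope == pytest.approx(1.5, rel=1e-9)

    def test_inserted_load_drop_triggers_at_insertion(self):
        """A -1 N/um drop over 20 points fires the default -0.45 N/um trigger."""
        cfg = FractureConfig()
        assert (cfg.unload_slope_threshold, cfg.slope_window) == (-0.45, 15)
        d = np.concatenate([np.linspace(0, 30, 301),
                            30 + np.arange(1, 21) * 0.5,
                            40 + np.arange(1, 101) * 0.1])
        p = np.concatenate([1.5 * np.linspace(0, 30, 301),
                            45 - np.arange(1, 21) * 0.5,
                            35 + np.arange(1, 101) * 0.15])
        rec = BendTestRecord(np.arange(1.0, len(d) + 1), np.maximum(p, 0), d)
        seg = segment_record(rec, cfg)
        assert len(seg.trigger_index) > 0
        assert 301 <= seg.trigger_index[0] <= 321

    def test_too_short_record(self):
        with pytest.raises(ValidationError):
            segment_record(_linear_ramp(n=10), FractureConfig(slope_window=15))


class TestPlasticArea:
    def _seg_with_slope(self, p, d, k):
        rec = BendTestRecord(np.arange(1.0, len(d) + 1), p, d)
        return SegmentedRecord(rec, [("loading", 0, len(d))], k,
                               np.array([], dtype=int))

    def test_events_on_one_elastic_line(self):
        k = 2.0
        d = np.linspace(0, 10, 101)
        seg = self._seg_with_slope(k * d, d, k)
        assert plastic_area(seg, 10, 90) == 0.0

    def test_parallelogram_oracle(self):
        """Pure plastic offset d_p at constant load P0 gives A_pl = P0 d_p."""
        k, p0, dp = 2.0, 10.0, 3.0
        d1 = np.linspace(0, p0 / k, 51)
        d2 = np.linspace(p0 / k, p0 / k + dp, 31)[1:]
        d = np.concatenate([d1, d2])
        p = np.concatenate([k * d1, np.full(len(d2), p0)])
        seg = self._seg_with_slope(p, d, k)
        a = plastic_area(seg, 50, len(d) - 1)
        assert a == pytest.approx(p0 * dp * 1e-6, rel=1e-12)

    def test_quadratic_segment_matches_analytic_integral(self):
        """Trapezoid + triangle correction vs the closed-form integral, <0.1%."""
        k = 2.0
        d = np.linspace(0, 10, 2001)
        p = 0.05 * d**2 + 0.5 * d          # smooth nonlinear loading path
        seg = self._seg_with_slope(p, d, k)
        i, j = 200, 1800
        di, dj = d[i], d[j]
        integral = (0.05 / 3) * (dj**3 - di**3) + 0.25 * (dj**2 - di**2)
        analytic = (integral + (p[i]**2 - p[j]**2) / (2 * k)) * 1e-6
        assert plastic_area(seg, i, j) == pytest.approx(analytic, rel=1e-3)

    def test_bad_slope_rejected(self):
        d = np.linspace(0, 10, 50)
        rec = BendTestRecord(np.arange(1.0, 51), 2 * d, d)
        with pytest.raises(ValidationError):
            SegmentedRecord(rec, [("loading", 0, 50)], 0.0, np.array([], dtype=int))


class TestBuildRCurve:
    def test_purely_elastic_single_event(self, geom, mat):
        """One event on the initial elastic line: J_pl = 0 and J_tot = J_el."""
        k = 1.9  # N/um
        d = np.linspace(0, 12, 241)
        rec = BendTestRecord(np.arange(1.0, 242), k * d, d)
        cracks = CrackLengthTable([200], [1520.0])
        rc = build_r_curve(rec, cracks, geom, mat)
        assert rc.j_pl[0] == 0.0
        assert rc.j_tot[0] == rc.j_el[0]
        assert rc.delta_a_um[0] == pytest.approx(20.0)

    def test_event_before_preload_rejected(self, geom, mat):
        d = np.linspace(0, 12, 241)
        rec = BendTestRecord(np.arange(1.0, 242), 1.9 * d, d)
        with pytest.raises(ValidationError):
            build_r_curve(rec, CrackLengthTable([1], [1510.0]), geom, mat)

    def test_duplicate_event_index_keeps_larger_length(self, geom, mat):
        d = np.linspace(0, 12, 241)
        rec = BendTestRecord(np.arange(1.0, 242), 1.9 * d, d)
        cracks = CrackLengthTable.__new__(CrackLengthTable)
        cracks.index = np.array([200, 200])
        cracks.a_um = np.array([1510.0, 1530.0])
        cracks.w_um = None
        rc = build_r_curve(rec, cracks, geom, mat)
        assert len(rc.delta_a_um) == 1
        assert rc.delta_a_um[0] == pytest.approx(30.0)

    def test_jtot_is_exact_sum(self, geom, mat):
        from bonequal.simulate import VirtualSpecimen, simulate_bend_test
        rec, table = simulate_bend_test(VirtualSpecimen(seed=7))
        rc = build_r_curve(rec, table, geom, mat)
        assert np.array_equal(rc.j_tot, rc.j_el + rc.j_pl)
        assert np.all(np.diff(rc.j_pl) >= 0)


class TestFitRCurve:
    def test_exact_quadratic_recovered(self):
        x = np.linspace(10, 700, 25)
        c = (120.0, 0.8, 1.2e-3)
        y = c[0] + c[1] * x + c[2] * x**2
        fit = fit_r_curve(x, y)
        np.testing.assert_allclose(fit.coeffs, c, rtol=1e-9)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        x = np.linspace(10, 700, 30)
        y = 100 + 0.5 * x + rng.normal(0, 5, 30)
        perm = rng.permutation(30)
        f1, f2 = fit_r_curve(x, y), fit_r_curve(x[perm], y[perm])
        np.testing.assert_allclose(f1.coeffs, f2.coeffs, rtol=1e-9)
        assert f1.ci_halfwidth(350.0) == pytest.approx(f2.ci_halfwidth(350.0))

    def test_insufficient_points(self):
        with pytest.raises(ValidationError):
            fit_r_curve([1, 2, 3], [1, 2, 3], degree=2)

    def test_ci_matches_statsmodels(self, rng):
        """Dual route: our covariance-based band vs statsmodels OLS."""
        x = np.linspace(10, 700, 20)
        y = 100 + 0.5 * x + 1e-3 * x**2 + rng.normal(0, 10, 20)
        fit = fit_r_curve(x, y, ci=0.95)
        design = sm.add_constant(np.column_stack([x, x**2]))
        res = sm.OLS(y, design).fit()
        np.testing.assert_allclose(fit.coeffs, res.params, rtol=1e-8)
        pred = res.get_prediction(design).conf_int(alpha=0.05)
        ours = fit.predict(x)
        np.testing.assert_allclose(ours - fit.ci_halfwidth(x), pred[:, 0], rtol=1e-6)
        np.testing.assert_allclose(ours + fit.ci_halfwidth(x), pred[:, 1], rtol=1e-6)

    def test_band_coverage_near_nominal(self, rng):
        """~95 % of 95 % pointwise bands should cover the true mean (MC)."""
        x = np.linspace(10, 700, 25)
        truth = 100 + 0.5 * x + 1e-3 * x**2
        x0 = 350.0
        t0 = 100 + 0.5 * x0 + 1e-3 * x0**2
        hits = 0
        reps = 1000
        for _ in range(reps):
            y = truth + rng.normal(0, 20, len(x))
            fit = fit_r_curve(x, y)
            hits += abs(fit.predict(x0) - t0) <= fit.ci_halfwidth(x0)
        assert hits / reps == pytest.approx(0.95, abs=0.025)
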
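"""Raman processing chain: despiking, averaging, baselines, band areas and
the six matrix indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonequal import DomainError, ValidationError
from bonequal.config import RamanConfig
from bonequal.raman import (GAUSS_FWHM, RamanMap, RamanSpectrum, average_map,
                            band_area, band_height, compute_indices,
                            expected_grid_count, linear_baseline,
                            remove_cosmic_rays)
from bonequal.simulate import RamanTruth, simulate_raman_map

AXIS = np.arange(800.0, 1800.5, 1.0)


def gaussian(w, center, sigma, area):
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((w - center) / sigma) ** 2)


class TestGrid:
    def test_inclusive_endpoint_formula(self):
        assert expected_grid_count(200, 30, 5) == 287
        assert expected_grid_count(10, 10, 5) == 9

    def test_map_count_validation(self, rng):
        w = AXIS[:50]
        with pytest.raises(ValidationError):
            RamanMap(w, rng.random((8, 50)), np.arange(8.0), np.zeros(8), 5.0)


class TestCosmicRays:
    def test_spike_free_unchanged(self, rng):
        y = gaussian(AXIS, 1000, 20, 100) + rng.normal(0, 0.1, len(AXIS))
        out = remove_cosmic_rays(RamanSpectrum(AXIS, y), 8.0)
        assert np.array_equal(out.intensity, y)

    @pytest.mark.parametrize("spike_channels", [(500,), (500, 501)])
    def test_spikes_removed(self, rng, spike_channels):
        """Single and adjacent double spikes are interpolated away."""
        sigma = 0.1
        clean = gaussian(AXIS, 1000, 20, 100)
        noisy = clean + rng.normal(0, sigma, len(AXIS))
        spiked = noisy.copy()
        for c in spike_channels:
            spiked[c] += 50 * sigma * len(spike_channels) * 2
        out = remove_cosmic_rays(RamanSpectrum(AXIS, spiked), 8.0)
        for c in spike_channels:
            assert abs(out.intensity[c] - clean[c]) < 3 * sigma
        # channels far from the spikes are untouched
        assert np.array_equal(out.intensity[:490], spiked[:490])


class TestAverage:
    def test_identical_spectra(self):
        w = AXIS[:100]
        y = gaussian(w, 850, 10, 5)
        rmap = RamanMap(w, np.tile(y, (9, 1)),
                        np.repeat(np.arange(3.0) * 5, 3),
                        np.tile(np.arange(3.0) * 5, 3), 5.0)
        out = average_map(rmap)
        np.testing.assert_allclose(out.intensity, y)

    def test_mean_of_two_is_midpoint(self):
        w = AXIS[:10]
        ints = np.stack([np.zeros(10), np.ones(10)])
        rmap = RamanMap(w, ints, np.array([0.0, 5.0]), np.zeros(2), 5.0)
        np.testing.assert_allclose(average_map(rmap).intensity, 0.5)


class TestBaselineAndBands:
    def test_straight_line_maps_to_zero(self):
        y = 3.0 + 0.01 * AXIS
        out = linear_baseline(RamanSpectrum(AXIS, y), (900, 1000))
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_gaussian_on_ramp_area_within_1pct(self):
        y = 5 + 0.002 * AXIS + gaussian(AXIS, 950, 8, 42.0)
        out = linear_baseline(RamanSpectrum(AXIS, y), (900, 1000))
        assert band_area(out, (900, 1000)) == pytest.approx(42.0, rel=0.01)

    def test_idempotent_for_compact_band(self):
        y = 5 + 0.002 * AXIS + gaussian(AXIS, 950, 6, 42.0)
        once = linear_baseline(RamanSpectrum(AXIS, y), (900, 1000))
        twice = linear_baseline(once, (900, 1000))
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-3)

    def test_region_outside_axis(self):
        with pytest.raises(DomainError):
            linear_baseline(RamanSpectrum(AXIS, AXIS * 0), (700, 900))

    def test_band_area_zero_and_additive(self):
        zero = RamanSpectrum(AXIS, np.zeros(len(AXIS)))
        assert band_area(zero, (900, 1000)) == 0.0
        y = gaussian(AXIS, 950, 8, 10.0)
        spec = RamanSpectrum(AXIS, y)
        whole = band_area(spec, (900, 1000))
        parts = band_area(spec, (900, 950)) + band_area(spec, (950, 1000))
        # adjacent subregions share the 950 sample; trapezoid areas add exactly
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_unit_area_gaussian(self):
        y = gaussian(AXIS, 950, 6, 1.0)
        assert band_area(RamanSpectrum(AXIS, y), (900, 1000)) == pytest.approx(
            1.0, abs=0.01)

    def test_band_height(self):
        y = gaussian(AXIS, 962, 5, 100.0)
        h = band_height(RamanSpectrum(AXIS, y), 962)
        assert h == pytest.approx(100 / (5 * math.sqrt(2 * math.pi)), rel=1e-6)


class TestIndices:
    def test_noiseless_recovery(self):
        truth = RamanTruth()
        spec = RamanSpectrum(AXIS, truth.clean_spectrum(AXIS))
        idx = compute_indices(spec).as_dict()
        for k, v in truth.expected_indices().items():
            assert idx[k] == pytest.approx(v, rel=0.02), k

    def test_crystallinity_gaussian_fwhm_identity(self):
        """nu1 as a sigma = 5 Gaussian: FWHM = 2.3548 * 5, crystallinity 1/FWHM."""
        truth = RamanTruth()
        spec = RamanSpectrum(AXIS, truth.clean_spectrum(AXIS))
        idx = compute_indices(spec)
        assert idx.crystallinity == pytest.approx(1.0 / (GAUSS_FWHM * 5.0),
                                                  rel=1e-3)

    def test_equal_subpeaks_ratio_one(self):
        truth = RamanTruth(amide_i=((1618.0, 4.5, 4.0), (1645.0, 6.0, 10.0),
                                    (1666.0, 6.0, 15.0), (1685.0, 6.0, 15.0)))
        spec = RamanSpectrum(AXIS, truth.clean_spectrum(AXIS))
        assert compute_indices(spec).amide1_sub_ratio == pytest.approx(1.0,
                                                                       abs=0.02)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_scale_invariance(self, scale):
        """All six indices are invariant under global intensity scaling."""
        truth = RamanTruth()
        base = truth.clean_spectrum(AXIS)
        i1 = compute_indices(RamanSpectrum(AXIS, base)).as_dict()
        i2 = compute_indices(RamanSpectrum(AXIS, scale * base)).as_dict()
        for k in i1:
            assert i2[k] == pytest.approx(i1[k], rel=1e-4), k

    def test_heights_variant(self):
        truth = RamanTruth()
        spec = RamanSpectrum(AXIS, truth.clean_spectrum(AXIS))
        cfg = RamanConfig(use_heights=True)
        idx = compute_indices(spec, cfg)
        # height ratio of Gaussians: (a_c/s_c) / (a_p/s_p)
        expected = (12.0 / 6.0) / (100.0 / 5.0)
        assert idx.carbonate_phosphate == pytest.approx(expected, rel=0.02)


class TestSimulatedMaps:
    def test_default_geometry_has_287_spectra(self):
        assert len(simulate_raman_map(snr=None, spike_rate=0, seed=0)) == 287

    def test_noiseless_map_exact_ratios(self):
        truth = RamanTruth()
        rmap = simulate_raman_map(truth, snr=None, spike_rate=0.0, seed=0)
        idx = compute_indices(average_map(rmap)).as_dict()
        exp = truth.expected_indices()
        for k in ("mmr_amide1", "mmr_amide3", "carbonate_phosphate",
                  "carbonate_amide1"):
            assert idx[k] == pytest.approx(exp[k], rel=0.005), k

    def test_determinism(self):
        a = simulate_raman_map(seed=11)
        b = simulate_raman_map(seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)
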
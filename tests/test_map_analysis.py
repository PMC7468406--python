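"""Vector-sum maps, ORI, OSI, receptive fields, and power spectra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rewiremap import map_analysis as ma
from rewiremap.cortex import random_initial_state
from rewiremap.map_analysis import (OrientationMap, band_power_fraction,
                                    fwhh, ori, orientation_histogram, osi,
                                    power_spectrum, probe_tuning,
                                    reconstruct_rf, vector_sum)
from rewiremap.stimulus_lgn import (LGNGrid, LGNRFParams, spatial_kernel,
                                    temporal_kernel)

ORIS12 = np.arange(12) * 15.0
ORIS6 = np.arange(6) * 30.0


def brute_force_vector_sum(responses, orientations):
    z = sum(r * np.exp(2j * np.deg2rad(th))
            for r, th in zip(responses, orientations))
    return np.rad2deg(np.angle(z)) / 2 % 180, abs(z)


class TestVectorSum:
    def test_single_bump_curve(self):
        pref, mag = vector_sum([1, 1, 1, 2, 1, 1], ORIS6)
        assert pref == pytest.approx(90.0)
        assert mag == pytest.approx(1.0)

    def test_flat_curve_cancels(self):
        _, mag = vector_sum(np.ones(6), ORIS6)
        assert mag == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance(self, rng):
        r = rng.uniform(0.1, 2.0, size=6)
        p0, m0 = vector_sum(r, ORIS6)
        p1, m1 = vector_sum(np.roll(r, 1), ORIS6)
        assert m1 == pytest.approx(m0)
        assert (p1 - p0) % 180 == pytest.approx(30.0) or m0 < 1e-12

    def test_matches_brute_force_complex_sum(self, rng):
        for _ in range(20):
            r = rng.uniform(0, 3, size=12)
            pref, mag = vector_sum(r, ORIS12)
            bp, bm = brute_force_vector_sum(r, ORIS12)
            assert mag == pytest.approx(bm, abs=1e-9)
            if bm > 1e-9:
                assert pref == pytest.approx(bp, abs=1e-6)

    def test_all_zero_curve_flagged(self):
        pref, mag = vector_sum(np.zeros(6), ORIS6)
        assert mag == 0.0 and np.isnan(pref)

    @given(st.lists(st.floats(0, 10), min_size=6, max_size=6))
    def test_magnitude_bounded_by_total_response(self, r):
        _, mag = vector_sum(r, ORIS6)
        assert mag <= sum(r) + 1e-9

    def test_needs_two_orientations(self):
        with pytest.raises(ValueError):
            vector_sum([1.0], [0.0])


class TestHistogramAndORI:
    def test_uniform_histogram(self):
        pref = np.repeat(ORIS6, 10)
        centers, area = orientation_histogram(pref, n_bins=6)
        np.testing.assert_allclose(area, 100.0 / 6)
        assert area[0] == pytest.approx(16.7, abs=0.05)
        assert ori(area, centers) == pytest.approx(0.0, abs=1e-12)

    def test_complete_over_representation(self):
        centers, area = orientation_histogram(np.full(40, 90.0), n_bins=6)
        assert ori(area, centers) == pytest.approx(1.0)

    def test_thirty_percent_in_vertical_bin(self):
        area = np.array([14.0, 14.0, 14.0, 30.0, 14.0, 14.0])
        assert ori(area) == pytest.approx(0.16, abs=5e-4)

    def test_invariant_under_permutation_of_other_bins(self, rng):
        area = np.array([10.0, 20.0, 5.0, 40.0, 15.0, 10.0])
        base = ori(area)
        others = [0, 1, 2, 4, 5]
        for _ in range(5):
            perm = area.copy()
            perm[others] = area[rng.permutation(others)]
            assert ori(perm) == pytest.approx(base)

    def test_under_representation_is_negative(self):
        area = np.array([25.0, 25.0, 25.0, 0.0, 12.5, 12.5])
        assert ori(area) < 0.0

    def test_wrong_bin_count_rejected(self):
        with pytest.raises(ValueError):
            ori(np.full(12, 100 / 12))

    def test_bins_centered_on_stimulus_orientations(self):
        # 100 deg falls in the 90-deg bin, 104 deg in the 105-deg bin (12 bins)
        _, area6 = orientation_histogram([100.0], n_bins=6)
        assert area6[3] == 100.0
        _, area12 = orientation_histogram([104.0], n_bins=12)
        assert area12[7] == 100.0

    def test_wraparound_binning(self):
        _, area = orientation_histogram([176.0], n_bins=6)
        assert area[0] == 100.0          # nearest center modulo 180 is 0


def triangle_curve(width, peak=90.0, floor=1.0, height=1.0):
    """Piecewise-linear tuning curve with FWHH exactly ``width``."""
    d = np.minimum(np.abs(ORIS12 - peak), 180 - np.abs(ORIS12 - peak))
    return np.maximum(floor, floor + height * (1 - d / width))


class TestOSI:
    def test_flat_curve_is_nonselective(self):
        assert osi(np.ones(12), ORIS12) == 0.0

    def test_textbook_value(self):
        # depth 1 - 1/2, width 60 deg: (1/2)(1 - 60/180) = 1/3
        curve = triangle_curve(60.0)
        assert fwhh(curve, ORIS12) == pytest.approx(60.0)
        assert osi(curve, ORIS12) == pytest.approx(1 / 3, abs=1e-9)

    def test_bimodal_curve_rejected(self):
        # two equal peaks: four half-height crossings -> OSI forced to zero
        curve = np.ones(12)
        curve[2] = 2.0
        curve[8] = 2.0
        assert osi(curve, ORIS12) == 0.0

    def test_monotone_in_width(self):
        widths = [30.0, 60.0, 90.0]
        vals = [osi(triangle_curve(w), ORIS12) for w in widths]
        assert vals[0] > vals[1] > vals[2]

    def test_fwhh_of_flat_curve_saturates(self):
        assert fwhh(np.ones(12), ORIS12) == 180.0

    def test_fwhh_of_cosine_curve(self):
        # 1 + cos(2 theta) crosses half height at 45 and 135 degrees
        curve = 1.0 + np.cos(np.deg2rad(2 * ORIS12))
        assert fwhh(curve, ORIS12) == pytest.approx(90.0, abs=1.0)

    @given(st.lists(st.floats(0, 5), min_size=12, max_size=12))
    def test_bounded_unit_interval(self, r):
        assert 0.0 <= osi(np.array(r), ORIS12) <= 1.0

    def test_negative_responses_rejected(self):
        with pytest.raises(ValueError):
            osi(np.array([-1.0] + [0.0] * 11), ORIS12)


class TestReceptiveFieldReconstruction:
    def make_state(self, geometry, cells, counts_per_cell):
        import numpy as np
        from rewiremap.cortex import SynapseState

        assignment = np.repeat(cells, counts_per_cell).astype(np.int32)
        assert assignment.size == geometry.n_sites
        full = np.tile(assignment, (geometry.n_neurons, 1))
        return SynapseState(full, geometry.lgn.n_cells)

    def test_single_input_reproduces_lgn_field(self, tiny_geometry, rf_params):
        grid = tiny_geometry.lgn
        state = self.make_state(tiny_geometry, [0], [tiny_geometry.n_sites])
        times, (ax, ay), frames = reconstruct_rf(state, 0, grid, rf_params)
        # cell 0 is ON non-lagged at the origin
        k = int(np.argmin(np.hypot(ax - 0, ay - 0)))
        expected = (tiny_geometry.n_sites
                    * spatial_kernel(1, 0.0, rf_params)
                    * temporal_kernel(1, times, rf_params))
        np.testing.assert_allclose(frames[:, k, k], expected, atol=1e-6)

    def test_linearity_in_counts(self, tiny_geometry, rf_params, rng):
        grid = tiny_geometry.lgn
        a = random_initial_state(tiny_geometry, rng)
        b = random_initial_state(tiny_geometry, rng)
        window = {"center": (0.25, 0.25), "half_width": 0.5}
        _, _, fa = reconstruct_rf(a, 2, grid, rf_params, **window)
        _, _, fb = reconstruct_rf(b, 2, grid, rf_params, **window)
        both = a.copy()
        both.counts = a.counts + b.counts   # direct superposition of counts
        _, _, fab = reconstruct_rf(both, 2, grid, rf_params, **window)
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_vertical_on_line_gives_vertical_subfield(self, rf_params):
        from rewiremap.cortex import CortexGeometry, SynapseState

        geo = CortexGeometry(nx=4, ny=4, n_sites=6, lgn=LGNGrid(8, 8))
        grid = geo.lgn
        # ON cells along a vertical line (constant x, varying y)
        cells = [grid.cell_index(0, 4, ky) for ky in (1, 2, 3, 4, 5, 6)]
        state = SynapseState(np.tile(np.array(cells, np.int32),
                                     (geo.n_neurons, 1)), grid.n_cells)
        times, (ax, ay), frames = reconstruct_rf(state, 0, grid, rf_params,
                                                 half_width=1.2)
        t_peak = int(np.argmax(np.abs(frames).sum(axis=(1, 2))))
        on = np.maximum(frames[t_peak] * np.sign(frames[t_peak].sum()), 0.0)
        xs, ys = np.meshgrid(ax, ay, indexing="ij")
        cx = (on * xs).sum() / on.sum()
        cy = (on * ys).sum() / on.sum()
        var_x = (on * (xs - cx) ** 2).sum() / on.sum()
        var_y = (on * (ys - cy) ** 2).sum() / on.sum()
        assert var_y > 2.0 * var_x      # elongated along the line axis


class TestProbeTuning:
    def test_probing_is_repeatable_and_readonly(self, tiny_geometry,
                                                tiny_twelve_table, rng):
        state = random_initial_state(tiny_geometry, rng)
        before = state.assignment.copy()
        c1 = probe_tuning(state, tiny_twelve_table)
        c2 = probe_tuning(state, tiny_twelve_table)
        np.testing.assert_array_equal(c1.responses, c2.responses)
        np.testing.assert_array_equal(state.assignment, before)

    def test_zero_coupling_gives_zero_curves(self, tiny_geometry,
                                             tiny_twelve_table, rng):
        state = random_initial_state(tiny_geometry, rng)
        curves = probe_tuning(state, tiny_twelve_table, v=0.0)
        assert np.all(curves.responses == 0.0)

    def test_orientations_cover_twelve(self, tiny_geometry,
                                       tiny_twelve_table, rng):
        state = random_initial_state(tiny_geometry, rng)
        curves = probe_tuning(state, tiny_twelve_table)
        np.testing.assert_allclose(curves.orientations, ORIS12)
        assert curves.responses.shape == (tiny_geometry.n_neurons, 12)
        assert np.all(curves.responses >= 0.0)


class TestPowerSpectrum:
    def test_constant_map_is_pure_dc(self):
        omap = OrientationMap(np.full(256, 45.0), np.ones(256), (16, 16))
        k, p = power_spectrum(omap)
        assert p[0] > 0 and np.all(p[1:] < 1e-20 * p[0])
        assert band_power_fraction(omap) == 0.0

    def test_random_map_spreads_power(self, rng):
        pref = rng.uniform(0, 180, size=1024)
        omap = OrientationMap(pref, np.ones(1024), (32, 32))
        frac = band_power_fraction(omap, (0.5, 3.5))
        # band holds ~3% of the pixels; white noise gives it ~that share
        assert frac < 0.15

    def test_bandpass_synthetic_map_peaks_at_filter_radius(self, rng):
        n, k0 = 32, 5.0
        z = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        fz = np.fft.fft2(z)
        kx = np.fft.fftfreq(n) * n
        kr = np.hypot(kx[:, None], kx[None, :])
        fz[np.abs(kr - k0) > 1.0] = 0.0
        zf = np.fft.ifft2(fz)
        omap = OrientationMap(np.rad2deg(np.angle(zf)) / 2 % 180,
                              np.abs(zf), (n, n))
        k, p = power_spectrum(omap)
        assert abs(int(np.argmax(p[1:])) + 1 - k0) <= 1
        assert band_power_fraction(omap, (4.0, 6.0)) > 0.9
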
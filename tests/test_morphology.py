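"""Cluster morphometry: ROIs, colocalisation, FWHM sizing, shape factors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myddotrack.morphology import (FWHM_FACTOR, colocalise_clusters,
                                   diameter_to_fwhm, fit_fwhm,
                                   fwhm_to_diameter, measure_clusters,
                                   shape_factor,
                                   shape_factor_from_area_perimeter,
                                   size_by_timepoint, spherical_fraction,
                                   threshold_reference_rois)
from myddotrack.simulate import simulate_cluster_masks


def _blob(img, cy, cx, amp=100.0, sigma=3.0):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


class TestReferenceRois:
    def test_two_puncta_give_two_rois(self):
        img = np.zeros((96, 96))
        _blob(img, 25, 25)
        _blob(img, 70, 60)
        assert len(threshold_reference_rois(img)) == 2

    def test_blank_image_gives_no_rois(self):
        assert threshold_reference_rois(np.zeros((32, 32))) == []

    def test_every_punctum_covered_by_exactly_one_roi(self):
        rng = np.random.default_rng(1)
        img = np.zeros((128, 128))
        centres = [(20, 20), (20, 90), (64, 55), (100, 30), (105, 100)]
        for cy, cx in centres:
            _blob(img, cy, cx)
        img += rng.normal(0, 1.0, img.shape)
        rois = threshold_reference_rois(img)
        for cy, cx in centres:
            covering = [r for r in rois
                        if r[0] <= cy < r[2] and r[1] <= cx < r[3]]
            assert len(covering) == 1


class TestColocalisation:
    def _clusters(self, centroids):
        return pd.DataFrame({
            "centroid_row_px": [c[0] for c in centroids],
            "centroid_col_px": [c[1] for c in centroids],
        })

    def test_centroid_inside_roi_is_retained(self):
        out = colocalise_clusters(self._clusters([(10, 10)]),
                                  [(5, 5, 15, 15)])
        assert bool(out["colocalised"][0])

    def test_centroid_outside_all_rois_is_excluded(self):
        out = colocalise_clusters(self._clusters([(40, 40)]),
                                  [(5, 5, 15, 15)])
        assert not bool(out["colocalised"][0])

    def test_filter_never_increases_cluster_count(self):
        rng = np.random.default_rng(2)
        cl = self._clusters(list(zip(rng.uniform(0, 60, 20),
                                     rng.uniform(0, 60, 20))))
        out = colocalise_clusters(cl, [(0, 0, 30, 30)])
        assert out["colocalised"].sum() <= len(cl)


class TestFwhm:
    def test_noiseless_gaussian_sigma_two(self):
        x = np.arange(41, dtype=float)
        y = 80.0 * np.exp(-(x - 20.0) ** 2 / (2 * 2.0 ** 2)) + 5.0
        fit = fit_fwhm(y)
        assert fit.sigma == pytest.approx(2.0, abs=1e-6)
        assert fit.fwhm == pytest.approx(4.710, abs=1e-3)

    def test_noisy_sigma_recovered_within_five_percent_median(self):
        rng = np.random.default_rng(3)
        x = np.arange(41, dtype=float)
        errs = []
        for _ in range(100):
            y = (100.0 * np.exp(-(x - 20.3) ** 2 / (2 * 2.0 ** 2)) + 10.0
                 + rng.normal(0, 5.0, x.size))
            errs.append(abs(fit_fwhm(y).sigma - 2.0) / 2.0)
        assert np.median(errs) < 0.05

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            fit_fwhm(np.full(21, 7.0))

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_fwhm([1.0, 2.0, 1.0])

    def test_fwhm_sigma_factor(self):
        assert FWHM_FACTOR == pytest.approx(2.3548200450309493)

    def test_diameter_from_fwhm(self):
        assert fwhm_to_diameter(235.48200450309493) == pytest.approx(100.0)
        assert fwhm_to_diameter(0.0) == 0.0
        d = 137.0
        assert fwhm_to_diameter(diameter_to_fwhm(d)) == pytest.approx(d)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            fwhm_to_diameter(-1.0)


class TestShapeFactor:
    def test_analytic_circle_square_rectangle(self):
        r = 3.7
        assert shape_factor_from_area_perimeter(
            math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)
        a = 5.0
        assert shape_factor_from_area_perimeter(a * a, 4 * a) \
            == pytest.approx(math.pi / 4)
        assert shape_factor_from_area_perimeter(9.0, 20.0) \
            == pytest.approx(36 * math.pi / 400)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0),
           a=st.floats(0.5, 50.0), b=st.floats(0.5, 50.0))
    def test_scale_invariance_for_rectangles(self, scale, a, b):
        sf1 = shape_factor_from_area_perimeter(a * b, 2 * (a + b))
        sf2 = shape_factor_from_area_perimeter(
            (a * scale) * (b * scale), 2 * scale * (a + b))
        assert sf1 == pytest.approx(sf2, rel=1e-9)

    def test_rasterised_disk_close_to_one(self):
        yy, xx = np.mgrid[0:49, 0:49].astype(float)
        mask = (yy - 24.2) ** 2 + (xx - 24.4) ** 2 <= 20.0 ** 2
        sf, area, perim = shape_factor(mask)
        assert sf >= 0.95
        assert sf <= 1.0  # capped

    def test_raster_convergence_towards_one(self):
        sfs = []
        for r in (6, 12, 24):
            yy, xx = np.mgrid[0:2 * r + 9, 0:2 * r + 9].astype(float)
            mask = (yy - r - 4.3) ** 2 + (xx - r - 4.1) ** 2 <= r * r
            sfs.append(shape_factor(mask, cap=False)[0])
        assert all(abs(s - 1.0) < 0.05 for s in sfs)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            shape_factor(np.zeros((5, 5), dtype=bool))
        two = np.zeros((9, 9), dtype=bool)
        two[1:3, 1:3] = True
        two[6:8, 6:8] = True
        with pytest.raises(ValueError, match="connected"):
            shape_factor(two)


class TestSphericalFraction:
    def test_all_circles(self):
        assert spherical_fraction([1.0, 1.0, 1.0]) == 1.0

    def test_mixed_population(self):
        sf = [1.0, 1.0, math.pi / 4, 0.3, 0.5]
        assert spherical_fraction(sf) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spherical_fraction([])

    def test_recovers_generator_circular_fraction(self):
        cs = simulate_cluster_masks(200, pixel_size_nm=10.0,
                                    circular_fraction=0.6, seed=3)
        sfs = [shape_factor(m)[0] for m in cs.masks]
        frac = spherical_fraction(sfs, tolerance=0.05)
        assert abs(frac - 0.6) <= 0.07


class TestMeasureClusters:
    def test_counts_and_areas(self):
        img = np.zeros((64, 64), dtype=bool)
        img[10:20, 10:20] = True  # 10x10 square
        yy, xx = np.mgrid[0:64, 0:64]
        img |= (yy - 45) ** 2 + (xx - 45) ** 2 <= 8 ** 2
        out = measure_clusters(img, pixel_size_nm=10.0)
        assert len(out) == 2
        square = out.iloc[(out["centroid_row_px"] - 14.5).abs().argmin()]
        assert square["area_um2"] == pytest.approx(100 * 1e-4, rel=1e-6)

    def test_minimum_size_filter(self):
        img = np.zeros((16, 16), dtype=bool)
        img[3, 3] = True  # single pixel: below min_pixels
        assert len(measure_clusters(img, 10.0)) == 0


class TestSizeByTimepoint:
    def _frame(self, cond, tp, values):
        return pd.DataFrame({"condition": cond, "timepoint": tp,
                             "fwhm_nm": values})

    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(150, 10, 40)
        df = pd.concat([self._frame("LPS", "30min", vals),
                        self._frame("Abeta", "30min", vals)])
        summary, tests = size_by_timepoint(df)
        assert tests["mean_difference"].iloc[0] == pytest.approx(0.0)
        assert tests["p_value"].iloc[0] == pytest.approx(1.0)

    def test_shifted_groups_report_the_shift(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(150, 10, 40)
        df = pd.concat([self._frame("LPS", "30min", vals),
                        self._frame("Abeta", "30min", vals + 25.0)])
        _, tests = size_by_timepoint(df)
        row = tests.iloc[0]
        sign = 1.0 if row["condition_a"] == "Abeta" else -1.0
        assert row["mean_difference"] == pytest.approx(sign * 25.0)

    def test_tiny_groups_excluded_from_tests(self):
        df = pd.concat([self._frame("LPS", "30min", [100.0]),
                        self._frame("Abeta", "30min", [1.0, 2.0, 3.0])])
        summary, tests = size_by_timepoint(df)
        assert len(tests) == 0
        assert len(summary) == 2

    def test_power_matches_closed_form(self):
        # unpaired t-test power for N(100,15) vs N(110,15), n=30/group
        n, sd, diff, alpha = 30, 15.0, 10.0, 0.05
        df_ = 2 * n - 2
        ncp = diff / (sd * math.sqrt(2.0 / n))
        tcrit = stats.t.ppf(1 - alpha / 2, df_)
        power = (1 - stats.nct.cdf(tcrit, df_, ncp)
                 + stats.nct.cdf(-tcrit, df_, ncp))
        rng = np.random.default_rng(6)
        hits = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(100, sd, n)
            b = rng.normal(110, sd, n)
            _, p = stats.ttest_ind(a, b)
            hits += p < alpha
        assert abs(hits / reps - power) < 0.06
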
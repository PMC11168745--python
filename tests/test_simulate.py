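"""Synthetic-data generator: lifetime law, geometry, events, rendering, masks."""

import numpy as np
import pytest

from myddotrack.config import SimulationConfig
from myddotrack.kinetics import lifetime_variance, mean_lifetime
from myddotrack.morphology import shape_factor
from myddotrack.simulate import (render_stack, simulate_cell,
                                 simulate_cluster_masks, simulate_dataset,
                                 simulate_events, simulate_lifetimes)


class TestLifetimeSampling:
    @pytest.mark.parametrize("k1,k2,expected_mean", [
        (0.01, 0.02, 150.0),   # (k1+k2)/(k1 k2)
        (0.01, 0.01, 200.0),   # Erlang-2 limit, 2/k
    ])
    def test_sample_mean_matches_model_mean(self, k1, k2, expected_mean):
        n = 100_000
        lt = simulate_lifetimes(n, k1, k2, seed=1)
        se = np.sqrt(lifetime_variance(k1, k2) / n)
        assert abs(lt.mean() - expected_mean) < 3 * se

    def test_sample_variance_matches_model_variance(self):
        lt = simulate_lifetimes(100_000, 0.005, 0.02, seed=2)
        expected = lifetime_variance(0.005, 0.02)
        assert abs(lt.var() - expected) / expected < 0.03

    def test_empirical_cdf_close_to_integrated_density(self):
        # oracle: CDF built by numerically integrating the density formula
        k1, k2 = 0.005, 0.02
        lt = simulate_lifetimes(10_000, k1, k2, seed=3)
        grid = np.linspace(0, lt.max() * 1.1, 20_000)
        pdf = k1 * k2 / (k2 - k1) * (np.exp(-k1 * grid) - np.exp(-k2 * grid))
        cdf = np.cumsum(pdf) * (grid[1] - grid[0])
        ecdf_x = np.sort(lt)
        ecdf_y = np.arange(1, lt.size + 1) / lt.size
        ks = np.max(np.abs(ecdf_y - np.interp(ecdf_x, grid, cdf)))
        assert ks < 0.02

    @pytest.mark.parametrize("k1,k2", [(0.0, 0.1), (-1.0, 0.1), (0.1, 0.0)])
    def test_non_positive_rates_rejected(self, k1, k2):
        with pytest.raises(ValueError):
            simulate_lifetimes(10, k1, k2, seed=0)


class TestCellGeometry:
    def test_static_cell_has_constant_centroid(self):
        cfg = SimulationConfig(image_shape=(5, 4, 96, 96), cell_radius=4.0)
        geom = simulate_cell(cfg)
        assert np.allclose(geom.centroids, geom.centroids[0])

    def test_drift_moves_centroid_linearly(self):
        cfg = SimulationConfig(image_shape=(5, 4, 96, 96), cell_radius=3.0,
                               drift_velocity=(0.01, 0.0))
        geom = simulate_cell(cfg)
        dx = np.diff(geom.centroids[:, 0])
        assert np.allclose(dx, 0.1)  # 0.01 um/s x 10 s frames
        assert np.allclose(np.diff(geom.centroids[:, 1]), 0.0)

    def test_boundary_points_lie_at_the_radius(self):
        cfg = SimulationConfig(image_shape=(2, 4, 160, 160), cell_radius=8.0)
        geom = simulate_cell(cfg)
        r = np.hypot(*(geom.boundaries[0] - geom.centroids[0]).T)
        assert np.max(np.abs(r - 8.0)) < cfg.pixel_size_xy

    def test_cell_larger_than_field_rejected(self):
        cfg = SimulationConfig(image_shape=(2, 4, 64, 64), cell_radius=8.0)
        with pytest.raises(ValueError, match="field of view"):
            simulate_cell(cfg)


class TestEvents:
    def _config(self, **kw):
        base = dict(image_shape=(50, 4, 96, 96), cell_radius=4.0,
                    nucleation_rate=0.05, formation_delay=100.0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_no_births_before_formation_delay(self):
        cfg = self._config(formation_delay=300.0, rng_seed=4)
        events = simulate_events(cfg, simulate_cell(cfg))
        assert all(e.birth_time >= 300.0 for e in events)

    def test_membrane_fraction_one_puts_all_events_in_band(self):
        cfg = self._config(membrane_fraction=1.0, rng_seed=5)
        geom = simulate_cell(cfg)
        events = simulate_events(cfg, geom)
        assert len(events) > 0
        for e in events:
            d = cfg.cell_radius - np.hypot(e.x - geom.centroids[0, 0],
                                           e.y - geom.centroids[0, 1])
            assert d <= 1.4 + 1e-9
            assert e.compartment == "membrane"

    def test_event_count_is_poisson_with_rate_times_duration(self):
        cfg = self._config(image_shape=(160, 4, 96, 96), nucleation_rate=0.01,
                           formation_delay=100.0, min_separation=0.0)
        geom = simulate_cell(cfg)
        counts = []
        for seed in range(100):
            c = SimulationConfig(**{**cfg.__dict__, "rng_seed": seed})
            counts.append(len(simulate_events(c, geom)))
        expected = 0.01 * 1500.0  # rate x post-delay duration
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_lifetimes_follow_the_two_step_mean(self):
        cfg = self._config(image_shape=(400, 4, 96, 96), nucleation_rate=0.2,
                           formation_delay=0.0, k1=0.01, k2=0.02,
                           min_separation=0.0, rng_seed=6)
        events = simulate_events(cfg, simulate_cell(cfg))
        lts = np.array([e.lifetime for e in events])
        mean = mean_lifetime(0.01, 0.02)
        se = np.sqrt(lifetime_variance(0.01, 0.02) / lts.size)
        assert abs(lts.mean() - mean) < 4 * se

    def test_minimum_separation_respected(self):
        # low enough density that dart throwing never needs its fallback
        cfg = self._config(nucleation_rate=0.02, min_separation=1.0,
                           rng_seed=7)
        events = simulate_events(cfg, simulate_cell(cfg))
        pos = np.array([[e.x, e.y] for e in events])
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.0 - 1e-9


class TestRendering:
    def test_zero_events_mean_matches_background_inside_cell(self):
        cfg = SimulationConfig(image_shape=(3, 8, 96, 96), cell_radius=4.0,
                               formation_delay=1e6, rng_seed=8)
        stack, events, geom = simulate_dataset(cfg)
        assert len(events) == 0
        z = 4  # inside the cell slab
        inside = stack[:, z][:, geom.masks[0]]
        assert abs(inside.mean() - cfg.background_level) < 1.0

    def test_single_punctum_is_brightest_at_its_voxel(self):
        cfg = SimulationConfig(image_shape=(8, 10, 96, 96), cell_radius=4.0,
                               nucleation_rate=0.5, formation_delay=10.0,
                               nucleation_duration=10.0, rng_seed=1)
        geom = simulate_cell(cfg)
        rng = np.random.default_rng(1)
        events = simulate_events(cfg, geom, rng=rng)
        events = events[:1]
        stack = render_stack(events, geom, cfg, noise=False)
        e = events[0]
        f = int(e.frames[0])
        iz, iy, ix = np.unravel_index(np.argmax(stack[f]), stack[f].shape)
        assert abs(ix - e.positions[0, 0] / cfg.pixel_size_xy) <= 1
        assert abs(iy - e.positions[0, 1] / cfg.pixel_size_xy) <= 1
        assert abs(iz - e.z / cfg.z_spacing) <= 1

    def test_identical_config_gives_bit_identical_output(self):
        cfg = SimulationConfig(image_shape=(4, 6, 64, 64), cell_radius=2.5,
                               nucleation_rate=0.2, formation_delay=0.0,
                               rng_seed=13)
        s1, e1, _ = simulate_dataset(cfg)
        s2, e2, _ = simulate_dataset(cfg)
        assert np.array_equal(s1, s2)
        assert len(e1) == len(e2)
        assert all(a.birth_time == b.birth_time and a.x == b.x
                   for a, b in zip(e1, e2))

    def test_invalid_amplitude_rejected_by_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(photon_amplitude=0.0)


class TestClusterMasks:
    def test_all_circular_means_all_shape_factors_one(self):
        cs = simulate_cluster_masks(20, circular_fraction=1.0, seed=0)
        assert np.all(cs.table["true_shape_factor"] == 1.0)
        assert np.all(cs.table["circular"])

    def test_circular_count_is_rounded_fraction(self):
        cs = simulate_cluster_masks(5, circular_fraction=0.4, seed=0)
        assert int(cs.table["circular"].sum()) == 2

    def test_invalid_circular_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_cluster_masks(5, circular_fraction=1.5, seed=0)

    def test_diameters_within_requested_range(self):
        cs = simulate_cluster_masks(50, size_range=(50.0, 500.0), seed=1)
        d = cs.table["true_diameter_nm"]
        assert d.min() >= 50.0 and d.max() <= 500.0

    def test_rasterised_disks_measure_nearly_circular(self):
        # morphometry stage applied to 100 rasterised disks of radius 10 px
        cs = simulate_cluster_masks(100, pixel_size_nm=10.0,
                                    circular_fraction=1.0,
                                    size_range=(200.0, 200.0), seed=2)
        sfs = [shape_factor(m)[0] for m in cs.masks]
        assert min(sfs) >= 0.95

    def test_irregular_true_shape_factor_below_one(self):
        cs = simulate_cluster_masks(30, circular_fraction=0.0, seed=3)
        sf = cs.table["true_shape_factor"]
        assert np.all((sf > 0) & (sf <= 0.85))
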
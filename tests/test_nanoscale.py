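"""Alpha-shape areas, SSD detection, synapse metrics, enrichment index."""

import numpy as np
import pytest

from conftest import make_table

from nanoorg.exceptions import (UndefinedDensityError, UndefinedEnrichmentError)
from nanoorg.geometry import alpha_shape, circle_equivalent_diameter
from nanoorg.nanoscale import (SsdConfig, SubsynapticDomain, detect_ssds,
                               enrichment_index, synapse_metrics)


def disc_points(n, radius, rng, center=(0.0, 0.0)):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestAlphaArea:
    def test_single_right_triangle(self):
        # circumradius = hypotenuse/2 = 70.7 <= 150, so the triangle is kept
        region = alpha_shape([(0, 0), (100, 0), (0, 100)], 150.0)
        assert region.area == pytest.approx(5000.0)
        assert len(region.triangles) == 1

    def test_two_points_degenerate(self):
        region = alpha_shape([(0, 0), (50, 50)], 150.0)
        assert region.area == 0.0
        assert len(region.triangles) == 0

    def test_collinear_points_degenerate(self):
        region = alpha_shape([(0, 0), (10, 10), (20, 20), (30, 30)], 150.0)
        assert region.area == 0.0

    def test_large_triangle_rejected_by_alpha(self):
        # circumradius of this triangle is 500 > 150: nothing retained
        region = alpha_shape([(0, 0), (1000, 0), (0, 1000)], 150.0)
        assert region.area == 0.0

    def test_uniform_disc_area_recovered(self):
        rng = np.random.default_rng(21)
        pts = disc_points(5000, 200.0, rng)
        region = alpha_shape(pts, 150.0)
        assert region.area == pytest.approx(np.pi * 200 ** 2, rel=0.05)

    def test_translation_rotation_invariance_and_scaling(self):
        rng = np.random.default_rng(22)
        pts = disc_points(400, 150.0, rng)
        base = alpha_shape(pts, 100.0).area
        shifted = alpha_shape(pts + [1000.0, -500.0], 100.0).area
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rotated = alpha_shape(pts @ rot.T, 100.0).area
        scaled = alpha_shape(pts * 3.0, 300.0).area  # alpha scales with coords
        assert shifted == pytest.approx(base, rel=1e-9)
        assert rotated == pytest.approx(base, rel=1e-6)
        assert scaled == pytest.approx(9.0 * base, rel=1e-9)

    def test_area_bounded_by_convex_hull(self):
        from scipy.spatial import ConvexHull
        rng = np.random.default_rng(23)
        pts = rng.uniform(0, 500, (200, 2))
        assert alpha_shape(pts, 80.0).area <= ConvexHull(pts).volume + 1e-9


class TestDetectSsds:
    def test_planted_cluster_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            center = np.array([40.0, -30.0])
            pts = np.vstack([rng.normal(center, 20.0, (80, 2)),
                             disc_points(40, 200.0, rng)])
            shape = alpha_shape(pts, 150.0)
            ssds = detect_ssds(pts, shape, seed=seed + 1000)
            if len(ssds) == 1 and np.hypot(*(np.array(ssds[0].peak) - center)) <= 30.0:
                hits += 1
        assert hits >= 18  # >= 90% of seeded runs

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 15.0, (60, 2)), disc_points(50, 150.0, rng)])
        shape = alpha_shape(pts, 150.0)
        a = detect_ssds(pts, shape, seed=7)
        b = detect_ssds(pts, shape, seed=7)
        assert len(a) == len(b)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.member_indices, t.member_indices)
            assert s.peak == t.peak
            assert s.area == t.area

    def test_members_disjoint_and_subset(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal([-60, 0], 15.0, (70, 2)),
                         rng.normal([80, 40], 15.0, (70, 2)),
                         disc_points(60, 250.0, rng)])
        shape = alpha_shape(pts, 150.0)
        ssds = detect_ssds(pts, shape, seed=5)
        all_members = np.concatenate([s.member_indices for s in ssds]) if ssds else []
        assert len(all_members) == len(set(all_members.tolist()))
        assert all(0 <= i < len(pts) for i in all_members)
        # peak is a member coordinate
        for s in ssds:
            assert any(np.allclose(s.peak, m) for m in s.member_xy)

    def test_empty_points_empty_list(self):
        shape = alpha_shape(np.zeros((0, 2)), 150.0)
        assert detect_ssds(np.zeros((0, 2)), shape, seed=0) == []

    def test_ssd_area_sum_below_synapse_area(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 20.0, (100, 2)), disc_points(60, 220.0, rng)])
        shape = alpha_shape(pts, 150.0)
        ssds = detect_ssds(pts, shape, seed=4)
        assert sum(s.area for s in ssds) <= shape.area + 1e-9


class TestSynapseMetrics:
    def _roi(self, pts):
        from shapely.geometry import box
        from nanoorg.roi_select import SynapseROI
        return SynapseROI(0, box(-1e5, -1e5, 1e5, 1e5),
                          locs_receptor=make_table(pts),
                          locs_scaffold=make_table(np.empty((0, 2))))

    def test_density_and_diameter_arithmetic(self):
        rng = np.random.default_rng(31)
        pts = disc_points(400, 203.5, rng)   # area ~ 130.1e3 nm^2
        m = synapse_metrics(self._roi(pts), "receptor", [])
        assert m.loc_density == pytest.approx(m.n_locs / m.total_area)
        assert m.circle_equivalent_diameter == pytest.approx(
            2 * np.sqrt(m.total_area / np.pi))
        assert np.isnan(m.mean_ssd_area)
        assert m.n_ssd == 0

    def test_printed_area_gives_diameter_in_reported_range(self):
        # 130.1e3 nm^2 mean gephyrin synapse area -> ~407 nm diameter
        assert circle_equivalent_diameter(130.1e3) == pytest.approx(407, abs=0.5)

    def test_ssd_ratio_arithmetic(self):
        rng = np.random.default_rng(32)
        pts = disc_points(500, 180.0, rng)
        ssds = [SubsynapticDomain(np.arange(5), pts[:5], 4000.0, (0, 0), 5),
                SubsynapticDomain(np.arange(5, 10), pts[5:10], 6000.0, (1, 1), 5)]
        m = synapse_metrics(self._roi(pts), "receptor", ssds)
        assert m.mean_ssd_area == pytest.approx(5000.0)
        assert m.ssd_to_synapse_area == pytest.approx(10000.0 / m.total_area)
        assert 0 <= m.ssd_to_synapse_area <= 1

    def test_zero_area_is_error(self):
        with pytest.raises(UndefinedDensityError):
            synapse_metrics(self._roi(np.zeros((2, 2))), "receptor", [])


class TestEnrichmentIndex:
    def test_all_locs_near_single_peak_closed_form(self):
        rng = np.random.default_rng(41)
        synapse = alpha_shape(disc_points(800, 300.0, rng), 150.0)
        locs_a = disc_points(200, 50.0, rng)   # all within 60 nm-ish of origin
        ssd = SubsynapticDomain(np.arange(1), np.zeros((1, 2)), 100.0, (0.0, 0.0), 1)
        res = enrichment_index(locs_a[np.hypot(*locs_a.T) <= 60.0], [ssd], synapse)
        assert res.enrichment_index == pytest.approx(
            synapse.area / (np.pi * 60.0 ** 2), rel=1e-9)

    def test_zero_a_locs_index_zero(self):
        rng = np.random.default_rng(42)
        synapse = alpha_shape(disc_points(500, 250.0, rng), 150.0)
        ssd = SubsynapticDomain(np.arange(1), np.zeros((1, 2)), 100.0, (0.0, 0.0), 1)
        assert enrichment_index(np.zeros((0, 2)), [ssd], synapse).enrichment_index == 0.0

    def test_no_reference_peaks_is_error(self):
        rng = np.random.default_rng(43)
        synapse = alpha_shape(disc_points(500, 250.0, rng), 150.0)
        with pytest.raises(UndefinedEnrichmentError):
            enrichment_index(np.zeros((5, 2)), [], synapse)

    def test_correlated_channels_exceed_anticorrelated(self):
        rng = np.random.default_rng(44)
        synapse = alpha_shape(disc_points(2000, 300.0, rng), 150.0)
        peak = (80.0, 0.0)
        ssd = SubsynapticDomain(np.arange(1), np.array([peak]), 100.0, peak, 1)
        co = rng.normal(peak, 25.0, (300, 2))
        anti = disc_points(300, 120.0, rng, center=(-150.0, 0.0))
        idx_co = enrichment_index(co, [ssd], synapse).enrichment_index
        idx_anti = enrichment_index(anti, [ssd], synapse).enrichment_index
        assert idx_co > 1.0
        assert idx_anti < 1.0
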
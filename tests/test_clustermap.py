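import numpy as np
import pytest

from nanoclust.clustermap import (
    Cluster,
    ClusterMap,
    area_to_diameter,
    binarize_and_label,
    build_cluster_map,
    calibrate_threshold,
    disc_area_weights,
    summarize_clusters,
)
from nanoclust.io_formats import LocalizationTable, RegionOfInterest
from nanoclust.synthetic_data import simulate_smlm


def flood_fill_label(binary):
    """Brute-force 8-connected component labeling."""
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            iy, ix = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = iy + dy, ix + dx
                    if (
                        0 <= ny < binary.shape[0]
                        and 0 <= nx < binary.shape[1]
                        and binary[ny, nx]
                        and not labels[ny, nx]
                    ):
                        labels[ny, nx] = current
                        stack.append((ny, nx))
    return labels, current


class TestAreaToDiameter:
    def test_reproduces_printed_bin_edge_diameters(self):
        assert round(area_to_diameter(5000.0)) == 80
        assert round(area_to_diameter(15000.0)) == 138

    def test_closed_form_circle(self):
        assert area_to_diameter(np.pi * 50.0**2) == pytest.approx(100.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            area_to_diameter(-1.0)


class TestDiscAreaWeights:
    def test_unity_in_interior_and_known_values_on_border(self, window):
        w_center = disc_area_weights([1500.0], [1500.0], 30.0, window)
        assert w_center[0] == pytest.approx(1.0)
        # disc centred on an edge: half inside
        w_edge = disc_area_weights([0.0], [1500.0], 30.0, window)
        assert w_edge[0] == pytest.approx(2.0)
        # disc centred on a corner: quarter inside
        w_corner = disc_area_weights([0.0], [0.0], 30.0, window)
        assert w_corner[0] == pytest.approx(4.0)

    def test_matches_monte_carlo_fraction(self, window, rng):
        # near-edge position: check against a Monte-Carlo disc fraction
        px, py, r = 12.0, 20.0, 30.0
        theta = rng.random(200000) * 2 * np.pi
        rad = np.sqrt(rng.random(200000)) * r
        inside = ((px + rad * np.cos(theta)) >= 0) & ((py + rad * np.sin(theta)) >= 0)
        w = disc_area_weights([px], [py], r, window)
        assert 1.0 / w[0] == pytest.approx(inside.mean(), abs=0.01)


class TestBuildClusterMap:
    def test_grid_dimensions(self, window):
        pts = np.array([[10.0, 10.0], [50.0, 50.0], [100.0, 30.0]])
        cmap = build_cluster_map(pts, window, grid_step=7.0)
        assert cmap.shape == (int(np.ceil(3000 / 7.0)),) * 2

    def test_maximum_near_single_cluster_center(self, window):
        table, truth = simulate_smlm(
            window=window, n_clusters=1, mean_molecules_per_cluster=40,
            sigma_c=20.0, n_background_molecules=60, seed=11,
        )
        cmap = build_cluster_map(table, window)
        iy, ix = np.unravel_index(np.argmax(cmap.values), cmap.shape)
        cx, cy = truth.cluster_centers[0]
        assert abs((ix + 0.5) * 10.0 - cx) <= 20.0
        assert abs((iy + 0.5) * 10.0 - cy) <= 20.0

    def test_methods_share_scale(self, window, rng):
        pts = rng.random((500, 2)) * 3000.0
        g = build_cluster_map(pts, window, method="grid")
        i = build_cluster_map(pts, window, method="interpolate")
        assert g.shape == i.shape
        assert g.values.min() >= 0 and i.values.min() >= 0

    def test_too_few_events(self, window):
        with pytest.raises(Exception):
            build_cluster_map(np.array([[1.0, 1.0]]), window)


class TestCalibrateThreshold:
    def test_deterministic(self, window):
        a = calibrate_threshold(150.0, window, n_sim=20, seed=2)
        b = calibrate_threshold(150.0, window, n_sim=20, seed=2)
        assert a.threshold == b.threshold

    def test_threshold_at_least_r0(self, window):
        cal = calibrate_threshold(150.0, window, n_sim=20, quantile=0.995, seed=3)
        assert cal.threshold >= 30.0

    def test_false_positive_pixel_rate_bounded(self, window):
        quantile = 0.99
        cal = calibrate_threshold(200.0, window, n_sim=20, quantile=quantile, seed=4)
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(5):
            pts = rng.random((1800, 2)) * 3000.0
            cmap = build_cluster_map(pts, window)
            rates.append(float((cmap.values > cal.threshold).mean()))
        assert np.mean(rates) <= (1 - quantile) + 0.02

    def test_parameter_validation(self, window):
        with pytest.raises(ValueError):
            calibrate_threshold(-5.0, window)
        with pytest.raises(ValueError):
            calibrate_threshold(100.0, window, quantile=0.4)
        with pytest.raises(ValueError):
            calibrate_threshold(100.0, window, n_sim=5)


class TestBinarizeAndLabel:
    def _map_from(self, values, step=10.0):
        roi = RegionOfInterest(0, 0, values.shape[1] * step, values.shape[0] * step)
        return ClusterMap(values=values.astype(float), grid_step=step, roi=roi, r0=30.0)

    def test_all_below_threshold_empty(self):
        cmap = self._map_from(np.zeros((20, 20)))
        assert binarize_and_label(cmap, 1.0, min_area=0.0) == []

    def test_component_area_definition(self):
        values = np.zeros((20, 20))
        values[5:8, 5:10] = 50.0  # 15 pixels
        cmap = self._map_from(values)
        clusters = binarize_and_label(cmap, 10.0, min_area=0.0)
        assert len(clusters) == 1
        assert clusters[0].area == 15 * 10.0**2

    def test_min_area_filter(self):
        values = np.zeros((20, 20))
        values[2, 2] = 50.0
        values[10:14, 10:14] = 50.0
        cmap = self._map_from(values)
        clusters = binarize_and_label(cmap, 10.0, min_area=1000.0)
        assert [c.area for c in clusters] == [1600.0]

    def test_labels_match_flood_fill(self, rng):
        values = (rng.random((40, 40)) > 0.6) * 50.0
        cmap = self._map_from(values)
        clusters = binarize_and_label(cmap, 10.0, min_area=0.0)
        ref_labels, n_ref = flood_fill_label(values > 10.0)
        assert len(clusters) == n_ref
        # identical pixel partitions
        ours = {frozenset(map(tuple, c.pixels.tolist())) for c in clusters}
        theirs = {
            frozenset(map(tuple, np.argwhere(ref_labels == k).tolist()))
            for k in range(1, n_ref + 1)
        }
        assert ours == theirs

    def test_event_assignment_by_footprint(self):
        values = np.zeros((20, 20))
        values[0:3, 0:3] = 50.0
        cmap = self._map_from(values)
        pts = LocalizationTable.from_arrays(x=[15.0, 150.0], y=[15.0, 150.0])
        clusters = binarize_and_label(cmap, 10.0, points=pts, min_area=0.0)
        assert clusters[0].n_events == 1
        assert list(clusters[0].member_events) == [0]


class TestSummarizeClusters:
    def test_degenerate_full_cover(self):
        roi = RegionOfInterest(0, 0, 1000.0, 1000.0)
        pix = np.argwhere(np.ones((100, 100), dtype=bool))
        cluster = Cluster(
            id=0, pixels=pix, pixel_size=10.0, area=1000.0 * 1000.0,
            centroid=(500.0, 500.0), n_events=10,
            member_events=np.arange(10),
        )
        pts = LocalizationTable.from_arrays(x=np.linspace(0, 999, 10), y=np.linspace(0, 999, 10))
        stats = summarize_clusters([cluster], pts, roi)
        assert stats.percent_events_in_clusters == pytest.approx(100.0)
        assert stats.relative_density == pytest.approx(1.0)
        assert stats.clusters_per_um2 == pytest.approx(1.0 / roi.area_um2)

    def test_boundary_area_in_small_bin(self):
        roi = RegionOfInterest(0, 0, 3000.0, 3000.0)
        mk = lambda i, a: Cluster(
            id=i, pixels=np.array([[0, 0]]), pixel_size=10.0, area=a, centroid=(5.0, 5.0)
        )
        # 5,000 nm^2 belongs to the lower bin (closed above); 15,000 to the middle
        clusters = [mk(0, 5000.0), mk(1, 15000.0), mk(2, 15001.0)]
        pts = LocalizationTable.from_arrays(x=[1.0], y=[1.0])
        stats = summarize_clusters(clusters, pts, roi)
        assert stats.size_bin_fractions == {
            "small": pytest.approx(1 / 3),
            "medium": pytest.approx(1 / 3),
            "large": pytest.approx(1 / 3),
        }

    def test_fractions_sum_to_one_and_events_bounded(self, window):
        table, _ = simulate_smlm(window=window, seed=21)
        cal = calibrate_threshold(len(table) / window.area_um2, window, n_sim=20, seed=22)
        cmap = build_cluster_map(table, window)
        clusters = binarize_and_label(cmap, cal, points=table)
        stats = summarize_clusters(clusters, table, window)
        if stats.size_bin_fractions:
            assert sum(stats.size_bin_fractions.values()) == pytest.approx(1.0)
        total_assigned = sum(c.n_events for c in clusters)
        assert total_assigned <= len(table)
        assert stats.percent_events_in_clusters == pytest.approx(
            100.0 * total_assigned / len(table)
        )

    def test_no_events_reported_missing(self):
        roi = RegionOfInterest(0, 0, 1000.0, 1000.0)
        pts = LocalizationTable.from_arrays(x=[], y=[])
        stats = summarize_clusters([], pts, roi)
        assert stats.percent_events_in_clusters is None
        assert stats.n_clusters == 0
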
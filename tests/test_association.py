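import numpy as np
import pytest

from nanoclust.association import (
    AssociationConfig,
    assign_tertiles,
    randomize_null,
    screen_association,
    size_effect_summary,
)
from nanoclust.clustermap import Cluster
from nanoclust.io_formats import CellMask, PixelImage
from nanoclust.synthetic_data import make_cell_mask

from conftest import make_disc_cluster, make_point_cluster


def area_cluster(cid, area):
    return Cluster(
        id=cid, pixels=np.array([[0, 0]]), pixel_size=10.0, area=float(area), centroid=(5.0, 5.0)
    )


class TestAssignTertiles:
    def test_exact_thirds(self):
        clusters = [area_cluster(i, a) for i, a in enumerate([1, 2, 3, 4, 5, 6])]
        bins, labels = assign_tertiles(clusters)
        assert labels == ["small", "small", "medium", "medium", "large", "large"]
        assert bins.cut_small_medium == 2.0
        assert bins.cut_medium_large == 4.0

    def test_remainder_goes_to_lower_bins(self):
        clusters = [area_cluster(i, a) for i, a in enumerate([10, 20, 30, 40, 50, 60, 70])]
        bins, _ = assign_tertiles(clusters)
        assert bins.counts == {"small": 3, "medium": 2, "large": 2}

    def test_input_order_invariance(self, rng):
        areas = rng.random(11) * 1e4
        clusters = [area_cluster(i, a) for i, a in enumerate(areas)]
        _, labels = assign_tertiles(clusters)
        perm = rng.permutation(11)
        _, labels_p = assign_tertiles([clusters[i] for i in perm])
        assert [labels[i] for i in perm] == labels_p

    def test_too_few_clusters(self):
        with pytest.raises(ValueError):
            assign_tertiles([area_cluster(0, 1.0), area_cluster(1, 2.0)])


def brute_force_flags(receptor_clusters, signaling_clusters, radius):
    """Pixel-by-pixel distance screen (edge mode)."""
    flags = []
    for rc in receptor_clusters:
        rp = (rc.pixels + 0.5) * rc.pixel_size  # (iy, ix) -> nm, both axes same scale
        hit = False
        for sc in signaling_clusters:
            sp = (sc.pixels + 0.5) * sc.pixel_size
            for y1, x1 in rp:
                for y2, x2 in sp:
                    if np.hypot(x1 - x2, y1 - y2) <= radius:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        flags.append(hit)
    return flags


class TestScreenAssociation:
    def test_overlapping_cluster_is_associated(self):
        rec = [make_disc_cluster(i, 600.0 + 700 * i, 600.0, 80.0) for i in range(3)]
        sig = [make_disc_cluster(9, 600.0, 600.0, 40.0)]
        cfg = AssociationConfig(search_radius=200.0)
        res = screen_association(rec, sig, None, cfg)
        assert bool(res.table["associated"][0]) is True

    def test_just_out_of_range_not_associated(self):
        ps = 20.0
        rec = [make_point_cluster(0, 10, 10, ps), make_point_cluster(1, 10, 40, ps), make_point_cluster(2, 40, 10, ps)]
        # nearest signaling pixel one pixel beyond the radius from cluster 0
        cfg = AssociationConfig(search_radius=100.0, mode="edge")
        sig = [make_point_cluster(9, 10, 10 + int(np.ceil((100.0 + ps) / ps)) + 1, ps)]
        res = screen_association(rec, sig, None, cfg)
        assert bool(res.table["associated"][0]) is False

    def test_flags_match_brute_force(self, rng):
        ps = 20.0
        rec, sig = [], []
        for i in range(6):
            iy, ix = rng.integers(5, 55, 2)
            rec.append(make_disc_cluster(i, (ix + 0.5) * ps, (iy + 0.5) * ps, 50.0, ps, (64, 64)))
        for j in range(4):
            iy, ix = rng.integers(5, 55, 2)
            sig.append(make_disc_cluster(10 + j, (ix + 0.5) * ps, (iy + 0.5) * ps, 30.0, ps, (64, 64)))
        cfg = AssociationConfig(search_radius=250.0, mode="edge")
        res = screen_association(rec, sig, None, cfg)
        assert list(res.table["associated"]) == brute_force_flags(rec, sig, 250.0)

    def test_monotone_in_search_radius(self, rng):
        ps = 20.0
        rec = [
            make_disc_cluster(i, 300.0 + 300 * i, 400.0 + 200 * (i % 3), 60.0, ps, (128, 128))
            for i in range(5)
        ]
        sig = [make_disc_cluster(9, 1500.0, 1500.0, 40.0, ps, (128, 128))]
        flagged_small = None
        for radius in (100.0, 400.0, 900.0, 1600.0):
            cfg = AssociationConfig(search_radius=radius)
            res = screen_association(rec, sig, None, cfg)
            flags = np.array(res.table["associated"])
            if flagged_small is not None:
                assert np.all(flags[flagged_small])  # once associated, stays associated
            flagged_small = flags

    def test_no_signaling_clusters_all_false(self):
        rec = [make_disc_cluster(i, 500.0 + 400 * i, 500.0, 60.0) for i in range(3)]
        res = screen_association(rec, [], None, AssociationConfig())
        assert not res.table["associated"].any()
        assert np.isnan(res.tertile_fractions["small"])

    def test_tertile_fractions_sum_to_one(self):
        rec = [make_disc_cluster(i, 500.0 + 400 * i, 500.0, 40.0 + 20 * i) for i in range(6)]
        sig = [make_disc_cluster(9, 700.0, 500.0, 40.0)]
        res = screen_association(rec, sig, None, AssociationConfig(search_radius=600.0))
        assert sum(res.tertile_fractions.values()) == pytest.approx(1.0)

    def test_nearby_intensity_region_sum(self):
        ps = 20.0
        img = PixelImage(np.ones((64, 64)), ps)
        rec = [make_point_cluster(0, 32, 32, ps), make_point_cluster(1, 5, 5, ps), make_point_cluster(2, 58, 58, ps)]
        cfg = AssociationConfig(search_radius=200.0, mode="centroid")
        res = screen_association(rec, [], img, cfg)
        # constant image: the summed intensity equals the pixel count of the
        # screening disc, close to pi R^2 / ps^2
        expected = np.pi * 200.0**2 / ps**2
        assert res.table["nearby_intensity"][0] == pytest.approx(expected, rel=0.05)


class TestRandomizeNull:
    def _setup(self, seed=0):
        mask = make_cell_mask(shape=(128, 128), axes=(1100.0, 900.0), pixel_size=20.0, seed=seed)
        rec = [
            make_disc_cluster(i, 1000.0 + 160 * i, 1100.0 + 90 * (i % 2), 40.0 + 12 * i, 20.0, (128, 128))
            for i in range(4)
        ]
        sig = [make_disc_cluster(10 + j, 900.0 + 220 * j, 1400.0, 50.0, 20.0, (128, 128)) for j in range(3)]
        img = PixelImage(np.ones((128, 128)), 20.0)
        return mask, rec, sig, img

    def test_replicates_preserve_count_and_areas_inside_mask(self):
        mask, rec, sig, img = self._setup()
        cfg = AssociationConfig(search_radius=300.0, n_null_reps=5, seed=1)
        null = randomize_null(sig, img, mask, rec, cfg)
        assert null.n_reps == 5
        # areas preserved exactly: the replicate screen uses rigid copies;
        # verify via a direct re-randomization of the cluster objects
        for rep in null.replicates:
            assert len(rep.table) == len(rec)

    def test_randomized_footprints_inside_mask(self):
        mask, rec, sig, _ = self._setup()
        from nanoclust.association import _valid_anchors

        for s in sig:
            rel = s.pixels - s.pixels.min(axis=0)
            anchors = _valid_anchors(mask.mask, rel)
            assert len(anchors) > 0
            for iy0, ix0 in anchors[:: max(1, len(anchors) // 50)]:
                assert mask.mask[rel[:, 0] + iy0, rel[:, 1] + ix0].all()

    def test_deterministic_for_fixed_seed(self):
        mask, rec, sig, img = self._setup()
        cfg = AssociationConfig(search_radius=300.0, n_null_reps=4, seed=9)
        n1 = randomize_null(sig, img, mask, rec, cfg)
        n2 = randomize_null(sig, img, mask, rec, cfg)
        for a, b in zip(n1.replicates, n2.replicates):
            assert a.table.equals(b.table)

    def test_unplaceable_cluster_named(self):
        mask = CellMask(np.eye(32, dtype=bool), 20.0)  # diagonal: no 2x2 fits
        rec = [make_point_cluster(i, i, i, 20.0) for i in range(3)]
        big = make_disc_cluster(77, 320.0, 320.0, 100.0, 20.0, (32, 32))
        with pytest.raises(ValueError, match="77"):
            randomize_null([big], None, mask, rec, AssociationConfig(n_null_reps=1, seed=0))

    def test_pointlike_association_matches_closed_form(self):
        # full-window mask, point-like signaling clusters: per-cluster
        # association probability is 1 - (1 - pi R^2 / A)^m
        ps = 10.0
        shape = (200, 200)
        mask = CellMask(np.ones(shape, dtype=bool), ps)
        positions = [(60, 60), (60, 100), (60, 140), (100, 60), (100, 100), (100, 140), (140, 60), (140, 100), (140, 140)]
        rec = [make_point_cluster(i, iy, ix, ps) for i, (iy, ix) in enumerate(positions)]
        m = 5
        sig = [make_point_cluster(50 + j, 3, 3, ps) for j in range(m)]
        R = 300.0
        cfg = AssociationConfig(search_radius=R, n_null_reps=300, seed=11)
        labels = ["small"] * 3 + ["medium"] * 3 + ["large"] * 3
        null = randomize_null(sig, None, mask, rec, cfg, tertile_labels=labels)
        per_rep = np.array([r.fraction_associated for r in null.replicates])
        p_theory = 1 - (1 - np.pi * R**2 / mask.area) ** m
        se = per_rep.std() / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - p_theory) <= max(4 * se, 0.02)


class TestSizeEffectSummary:
    def test_self_comparison_zero_difference(self):
        mask, rec, sig, img = TestRandomizeNull()._setup()
        # find a single-replicate null whose replicate associates at least
        # one cluster, then feed that replicate back in as "observed"
        for seed in range(30):
            cfg = AssociationConfig(search_radius=300.0, n_null_reps=1, seed=seed)
            null = randomize_null(sig, img, mask, rec, cfg)
            if null.replicates[0].fraction_associated > 0:
                break
        else:
            pytest.fail("no replicate with an associated cluster")
        table = size_effect_summary(null.replicates[0], null)
        np.testing.assert_allclose(table["difference"].to_numpy(dtype=float), 0.0, atol=1e-12)

    def test_enriched_large_tertile_detected(self, rng):
        # signaling clusters deliberately seeded at the largest receptor
        # clusters: observed large-tertile fraction should beat the null mean
        mask = make_cell_mask(shape=(128, 128), axes=(1150.0, 1000.0), pixel_size=20.0, seed=4)
        radii = np.linspace(30, 110, 9)
        centers = []
        for r in radii:
            for _ in range(1000):
                c = (rng.uniform(700, 1900), rng.uniform(700, 1800))
                if all(np.hypot(c[0] - p[0], c[1] - p[1]) > 330 for p in centers):
                    break
            centers.append(c)
        rec = [make_disc_cluster(i, cx, cy, r, 20.0, (128, 128)) for i, ((cx, cy), r) in enumerate(zip(centers, radii))]
        _, labels = None, None
        big3 = sorted(rec, key=lambda c: -c.area)[:3]
        sig = [make_disc_cluster(30 + j, c.centroid[0] + 80.0, c.centroid[1], 30.0, 20.0, (128, 128)) for j, c in enumerate(big3)]
        img = PixelImage(np.ones((128, 128)), 20.0)
        cfg = AssociationConfig(search_radius=150.0, n_null_reps=60, seed=5)
        observed = screen_association(rec, sig, img, cfg)
        null = randomize_null(sig, img, mask, rec, cfg)
        table = size_effect_summary(observed, null)
        assert table.loc["large", "observed_fraction"] > table.loc["large", "null_mean_fraction"]
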
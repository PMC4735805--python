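"""Cluster detection, membrane filtering and distance statistics vs. brute-force oracles."""

import numpy as np
import pytest

from idisc.clusters import (
    DistanceRecord,
    MembraneMask,
    ReconstructedImage,
    binarize,
    clusters_from_ellipses,
    detect_clusters,
    distance_summary,
    filter_by_membrane,
    nn_distances,
)
from idisc.geometry import Ellipse, ellipse_edge_distance
from idisc.synthetic import gen_ellipse_field, render_localization_image


def disc_mask(shape, center_rc, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2


def flood_count(mask):
    """Brute-force 8-connected component labelling (test oracle)."""
    mask = mask.copy()
    sizes = []
    while mask.any():
        r, c = np.argwhere(mask)[0]
        stack, comp = [(r, c)], 0
        mask[r, c] = False
        while stack:
            i, j = stack.pop()
            comp += 1
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < mask.shape[0] and 0 <= jj < mask.shape[1] and mask[ii, jj]:
                        mask[ii, jj] = False
                        stack.append((ii, jj))
        sizes.append(comp)
    return sizes


class TestBinarize:
    def test_all_zero_image_gives_empty_mask(self):
        img = ReconstructedImage(np.zeros((1, 20, 20)), channel_names=("ch0",))
        assert not binarize(img, "ch0", 1, 0.5).any()

    def test_idempotent_on_binary_input(self):
        data = np.zeros((1, 30, 30))
        data[0, 5:10, 5:10] = 1.0
        img = ReconstructedImage(data)
        mask = binarize(img, "ch0", 0, 0.5)
        assert np.array_equal(mask, data[0].astype(bool))

    def test_unknown_method_rejected(self):
        img = ReconstructedImage(np.zeros((1, 5, 5)))
        with pytest.raises(ValueError):
            binarize(img, "ch0", 0, "triangle")

    def test_mask_covers_true_ellipse_pixels(self):
        field = gen_ellipse_field(4000, 0, 5, seed=0, min_clearance_nm=150, edge_margin_nm=250)
        img = render_localization_image(field, 20.0, density=0.05, precision_nm=5.0, seed=0)
        mask = binarize(img, "query", 1, "otsu")
        # pixels whose center is inside a true ellipse
        rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        x, y = (cols + 0.5) * 20.0, (rows + 0.5) * 20.0
        inside = np.zeros_like(mask)
        for e in field.query_ellipses:
            M = e.conic_matrix()
            v = (
                M[0, 0] * x**2 + 2 * M[0, 1] * x * y + M[1, 1] * y**2
                + 2 * M[0, 2] * x + 2 * M[1, 2] * y + M[2, 2]
            )
            inside |= v <= 0
        assert mask[inside].mean() >= 0.95


class TestDetect:
    def test_single_disc_morphology(self):
        mask = disc_mask((40, 40), (20, 20), 5)
        cl = detect_clusters(mask, pixel_nm=20.0)
        assert len(cl) == 1
        area_px = cl[0].area_nm2 / 20.0**2
        assert area_px == pytest.approx(np.pi * 25, rel=0.10)
        assert cl[0].circularity > 0.85
        assert np.allclose(cl[0].centroid_nm, [(20.5) * 20, (20.5) * 20], atol=20)

    def test_two_separate_discs(self):
        mask = disc_mask((60, 60), (15, 15), 5) | disc_mask((60, 60), (45, 45), 5)
        assert len(detect_clusters(mask, pixel_nm=20.0)) == 2

    def test_component_sizes_match_flood_fill_oracle(self, rng):
        mask = rng.uniform(size=(50, 50)) < 0.25
        cl = detect_clusters(mask, pixel_nm=20.0, min_size=3)
        oracle = [s for s in flood_count(mask) if s >= 3]
        assert sorted(len(c.pixels) for c in cl) == sorted(oracle)
        # pixel conservation: detected + sub-min-size = all foreground
        small = sum(s for s in flood_count(mask) if s < 3)
        assert sum(len(c.pixels) for c in cl) + small == mask.sum()

    def test_empty_mask_empty_list(self):
        assert detect_clusters(np.zeros((10, 10), bool), pixel_nm=20.0) == []

    def test_3d_volume_and_counting(self):
        mask = np.zeros((4, 20, 20), bool)
        mask[1:3, 5:8, 5:8] = True  # 2*3*3 = 18 voxels
        mask[0, 15, 15] = True
        cl = detect_clusters(mask, pixel_nm=20.0, z_step_nm=50.0, min_size=2)
        assert len(cl) == 1
        assert cl[0].volume_nm3 == pytest.approx(18 * 20 * 20 * 50)

    def test_translation_invariance(self):
        mask = disc_mask((50, 50), (20, 20), 6)
        shifted = np.roll(mask, (7, 4), axis=(0, 1))
        a = detect_clusters(mask, pixel_nm=20.0)[0]
        b = detect_clusters(shifted, pixel_nm=20.0)[0]
        assert b.area_nm2 == a.area_nm2
        assert np.allclose(b.centroid_nm - a.centroid_nm, [4 * 20.0, 7 * 20.0])


class TestMembraneFilter:
    line = MembraneMask(np.array([[0.0, 500.0], [4000.0, 500.0]]), 500.0)

    def test_keep_and_drop(self):
        keep = clusters_from_ellipses([Ellipse(1000, 900, 50, 50)], "q")  # 400 nm away
        drop = clusters_from_ellipses([Ellipse(1000, 1100, 50, 50)], "q")  # 600 nm away
        assert len(filter_by_membrane(keep, self.line)) == 1
        assert len(filter_by_membrane(drop, self.line)) == 0

    def test_matches_brute_force_point_segment_distance(self, rng):
        poly = rng.uniform(0, 4000, (6, 2))
        mask = MembraneMask(poly, 300.0)
        cl = clusters_from_ellipses(
            [Ellipse(x, y, 30, 30) for x, y in rng.uniform(0, 4000, (80, 2))], "q"
        )

        def seg_dist(p, a, b):
            ab, ap = b - a, p - a
            t = np.clip(ap @ ab / (ab @ ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        expected = [
            c
            for c in cl
            if min(seg_dist(c.centroid_nm[:2], poly[i], poly[i + 1]) for i in range(5)) <= 300.0
        ]
        got = filter_by_membrane(cl, mask)
        assert [c.id for c in got] == [c.id for c in expected]

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            MembraneMask(np.array([[0.0, 0.0]]))


class TestDistances:
    def test_two_discs_centroid_and_edge(self):
        q = clusters_from_ellipses([Ellipse(0, 0, 100, 100)], "q")
        r = clusters_from_ellipses([Ellipse(300, 0, 100, 100)], "r")
        rec = nn_distances(q, r)[0]
        assert rec.centroid_to_centroid_nm == pytest.approx(300.0)
        assert rec.edge_to_edge_nm == pytest.approx(100.0, abs=0.1)
        assert not rec.contact

    def test_overlap_flagged_as_contact(self):
        q = clusters_from_ellipses([Ellipse(0, 0, 100, 100)], "q")
        r = clusters_from_ellipses([Ellipse(120, 0, 100, 100)], "r")
        rec = nn_distances(q, r)[0]
        assert rec.edge_to_edge_nm <= 0
        assert rec.contact

    def test_matches_brute_force_scan(self, rng):
        qs = clusters_from_ellipses(
            [
                Ellipse(x, y, rng.uniform(30, 120), rng.uniform(30, 120), rng.uniform(0, 180))
                for x, y in rng.uniform(0, 5000, (25, 2))
            ],
            "q",
        )
        rs = clusters_from_ellipses(
            [
                Ellipse(x, y, rng.uniform(30, 120), rng.uniform(30, 120), rng.uniform(0, 180))
                for x, y in rng.uniform(0, 5000, (25, 2))
            ],
            "r",
        )
        records = nn_distances(qs, rs)
        for q, rec in zip(qs, records):
            dists = [(ellipse_edge_distance(q.ellipse, r.ellipse), r.id) for r in rs]
            best = min(dists, key=lambda t: (t[0], t[1]))
            assert rec.reference_id == best[1]
            assert rec.edge_to_edge_nm == pytest.approx(best[0], abs=1e-9)

    def test_self_excluded_in_same_species_analysis(self):
        cl = clusters_from_ellipses([Ellipse(0, 0, 50, 50), Ellipse(500, 0, 50, 50)], "q")
        recs = nn_distances(cl, cl)
        assert [r.reference_id for r in recs] == [1, 0]

    def test_empty_reference_rejected(self):
        q = clusters_from_ellipses([Ellipse(0, 0, 50, 50)], "q")
        with pytest.raises(ValueError):
            nn_distances(q, [])

    def test_raster_edge_distance_close_to_geometry(self):
        # two rendered discs radius 100 nm (5 px), centers 600 nm apart
        mask = disc_mask((50, 50), (25, 10), 5) | disc_mask((50, 50), (25, 40), 5)
        cl = detect_clusters(mask, pixel_nm=20.0)
        rec = nn_distances([cl[0]], [cl[1]])[0]
        assert rec.centroid_to_centroid_nm == pytest.approx(600.0, abs=20)
        assert rec.edge_to_edge_nm == pytest.approx(600 - 200, abs=30)


class TestSummary:
    def make(self, edges):
        return [DistanceRecord(i, 0, abs(e) + 100, e) for i, e in enumerate(edges)]

    def test_worked_example(self):
        s = distance_summary(self.make([-10, -5, 40, 150, 250, 600]), 100.0)
        assert s["contact_fraction"] == pytest.approx(2 / 6)
        assert s["bin_fractions"][0] == pytest.approx(1 / 6)  # (0, 100]
        assert s["bin_fractions"][1] == pytest.approx(1 / 6)  # (100, 200]
        assert s["contact_fraction"] + s["bin_fractions"].sum() == pytest.approx(1.0)

    def test_all_contact(self):
        s = distance_summary(self.make([-5, -1, 0]), 100.0)
        assert s["contact_fraction"] == 1.0

    def test_right_closed_bins(self):
        s = distance_summary(self.make([100.0, 100.5]), 100.0)
        assert s["bin_fractions"][0] == pytest.approx(0.5)  # 100 in (0, 100]
        assert s["bin_fractions"][1] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_summary([], 100.0)


def test_roundtrip_detection_recovers_truth():
    """gen field -> render -> binarize -> detect recovers cluster count
    exactly and centroids within one pixel, across seeds."""
    for seed in range(5):
        field = gen_ellipse_field(
            8000, 0, 8, seed=seed, min_clearance_nm=150, edge_margin_nm=250
        )
        img = render_localization_image(field, 20.0, density=0.02, precision_nm=10.0, seed=seed)
        mask = binarize(img, "query", 1, "otsu")
        cl = detect_clusters(mask, pixel_nm=20.0, min_size=4, channel="query")
        assert len(cl) == len(field.query_ellipses)
        true_c = np.array([[e.cx, e.cy] for e in field.query_ellipses])
        det_c = np.array([c.centroid_nm for c in cl])
        for t in true_c:
            assert np.min(np.linalg.norm(det_c - t, axis=1)) <= 20.0


class TestSummaryProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-500.0, 2000.0, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_always_sum_to_one(self, edges):
        recs = [DistanceRecord(i, 0, abs(e) + 1, e) for i, e in enumerate(edges)]
        s = distance_summary(recs, 100.0)
        assert s["contact_fraction"] + s["bin_fractions"].sum() == pytest.approx(1.0)
        assert s["contact_fraction"] == np.mean([e <= 0 for e in edges])
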
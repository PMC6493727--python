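import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluorodroplet.contour_detection import (
    CLASS_PRECEDENCE,
    ColorBoundary,
    Contour,
    ContourParams,
    build_color_mask,
    canny_edges,
    default_boundaries,
    extract_contours,
    fill_interior,
    filter_by_area,
    masked_grayscale,
    morph_dilate,
    morph_erode,
    project_labels_to_mask,
    resolve_class_conflicts,
    segment_touching,
)

from _oracles import brute_dilate, brute_erode


def _img16(bgr8, shape=(1, 1)):
    """Uniform image from an 8-bit B,G,R triple lifted to 16-bit."""
    px = np.empty(shape + (3,), dtype=np.uint16)
    px[:] = np.array(bgr8, dtype=np.uint16) * 257
    return px


class TestColorMask:
    live = ColorBoundary.default("live")

    def test_pure_green_in_live_window(self):
        assert build_color_mask(_img16((0, 255, 0)), self.live).all()

    def test_yellow_excluded_from_live(self):
        # R channel 255 exceeds the live upper bound of 153
        assert not build_color_mask(_img16((0, 255, 255)), self.live).any()

    def test_black_excluded_everywhere(self):
        for cls in ("live", "dead", "overlap", "eu_np", "tb_np"):
            b = ColorBoundary.default(cls)
            assert not build_color_mask(_img16((0, 0, 0)), b).any()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        px=st.tuples(*[st.integers(0, 255)] * 3),
        lo=st.tuples(*[st.integers(0, 255)] * 3),
        width=st.tuples(*[st.integers(0, 255)] * 3),
    )
    def test_membership_is_componentwise_interval_test(self, px, lo, width):
        up = tuple(min(255, l + w) for l, w in zip(lo, width))
        boundary = ColorBoundary("custom", lo, up)
        mask = build_color_mask(_img16(px), boundary)
        expected = all(l * 257 <= p * 257 <= u * 257
                       for p, l, u in zip(px, lo, up))
        assert bool(mask[0, 0]) == expected

    def test_invalid_boundary(self):
        with pytest.raises(ValueError):
            ColorBoundary("custom", (10, 0, 0), (5, 255, 255))


class TestMaskedGrayscale:
    def test_zero_mask_zero_output(self):
        img = _img16((100, 200, 50), shape=(8, 8))
        out = masked_grayscale(img, np.zeros((8, 8), dtype=bool))
        assert not out.any()

    def test_uniform_gray_preserved(self):
        px = np.full((8, 8, 3), 1000, dtype=np.uint16)
        out = masked_grayscale(px, np.ones((8, 8), dtype=bool))
        assert (out == 1000).all()

    def test_luminance_is_monotone_in_green(self):
        px = np.zeros((1, 2, 3), dtype=np.uint16)
        px[0, 0, 1], px[0, 1, 1] = 2000, 1000
        out = masked_grayscale(px, np.ones((1, 2), dtype=bool), kernel=1)
        assert out[0, 0] > out[0, 1]

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            masked_grayscale(_img16((0, 0, 0), (4, 4)),
                             np.ones((5, 5), dtype=bool))


class TestCanny:
    def test_uniform_image_no_edges(self):
        assert not canny_edges(np.full((16, 16), 9000.0)).any()

    def test_vertical_step_single_line(self):
        from scipy import ndimage as ndi

        img = np.zeros((16, 16))
        img[:, 8:] = 40000.0
        edges = canny_edges(img)
        _, n = ndi.label(edges, structure=np.ones((3, 3)))
        assert n == 1
        cols = np.nonzero(edges)[1]
        assert np.all(np.abs(cols - 7.5) <= 1.5)

    def test_threshold_above_gradient_empty(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 100.0
        assert not canny_edges(img, t_min=1e6, t_max=2e6).any()

    def test_inverted_thresholds_fatal(self):
        with pytest.raises(ValueError):
            canny_edges(np.zeros((8, 8)), t_min=10, t_max=5)


class TestMorphology:
    def test_point_dilates_to_block(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        out = morph_dilate(m, 3, 1)
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_erosion_inverts_dilation_of_point(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        assert np.array_equal(morph_erode(morph_dilate(m, 3, 1), 3, 1), m)

    def test_gap_closing(self):
        from scipy import ndimage as ndi
        from skimage.draw import circle_perimeter

        m = np.zeros((40, 40), dtype=bool)
        rr, cc = circle_perimeter(20, 20, 12)
        m[rr, cc] = True
        m[8, 19:21] = False  # 2 px break in the ring
        closed = morph_erode(morph_dilate(m, 3, 1), 3, 1)
        filled = fill_interior(closed)
        assert filled.sum() > 300  # interior filled => ring was closed
        _, n = ndi.label(filled, structure=np.ones((3, 3)))
        assert n == 1

    def test_matches_minkowski_oracle(self, rng):
        for _ in range(5):
            m = rng.random((16, 16)) < 0.3
            assert np.array_equal(morph_dilate(m, 3, 1), brute_dilate(m, 3))
            assert np.array_equal(morph_erode(m, 3, 1), brute_erode(m, 3))


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - center[0], yy - center[1]) <= radius


class TestSegmentation:
    def test_disjoint_disks_two_labels(self):
        m = _disk_mask((60, 60), (15, 15), 8) | _disk_mask((60, 60), (45, 45), 8)
        labels = segment_touching(m)
        assert len(np.unique(labels)) - 1 == 2

    def test_touching_disks_split_near_bisector(self):
        m = _disk_mask((40, 60), (22, 20), 8) | _disk_mask((40, 60), (34, 20), 8)
        labels = segment_touching(m)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        assert len(ids) == 2
        one_disk = _disk_mask((40, 60), (22, 20), 8).sum()
        for n in counts:
            assert abs(n - one_disk) / one_disk < 0.15

    def test_empty_mask_no_labels(self):
        assert segment_touching(np.zeros((10, 10), dtype=bool)).max() == 0


class TestExtractContours:
    def test_square_area_and_centroid(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:16, 4:16] = 1
        (c,) = extract_contours(labels, "live")
        assert c.area == 144
        assert c.centroid == (9.5, 9.5)

    def test_convex_disk_boundary_untouched(self):
        labels = _disk_mask((30, 30), (15, 15), 9).astype(np.int32)
        (c,) = extract_contours(labels, "live", ContourParams())
        # a convex region has no defects deeper than rasterization jitter,
        # so the traced (dense, many-vertex) boundary is not hull-replaced
        assert len(c.boundary) > 20
        assert c.area == int(labels.sum())

    def test_crescent_hull_adjustment(self):
        big = _disk_mask((40, 40), (20, 20), 12)
        bite = _disk_mask((40, 40), (32, 20), 9)
        crescent = (big & ~bite).astype(np.int32)
        params = ContourParams(hull_defect_depth=4.0)
        (c,) = extract_contours(crescent, "live", params)
        # after hull replacement the boundary polygon must be convex
        from scipy.spatial import ConvexHull

        hull = ConvexHull(c.boundary)
        assert len(hull.vertices) == len(c.boundary)
        assert c.area == int(crescent.sum())  # pixel set unchanged


class TestAreaFilter:
    def test_inclusive_cell_threshold(self):
        contours = [
            Contour(i, "live", np.zeros((a, 2), dtype=int), (0.0, 0.0),
                    np.zeros((1, 2)))
            for i, a in enumerate([100, 129, 130, 150])
        ]
        kept = filter_by_area(contours, 130)
        assert sorted(c.area for c in kept) == [130, 150]

    def test_inclusive_np_threshold(self):
        contours = [
            Contour(i, "eu_np", np.zeros((a, 2), dtype=int), (0.0, 0.0),
                    np.zeros((1, 2)))
            for i, a in enumerate([149, 150, 170])
        ]
        kept = filter_by_area(contours, 150)
        assert sorted(c.area for c in kept) == [150, 170]

    def test_idempotent_and_empty(self):
        assert filter_by_area([], 130) == []
        contours = [
            Contour(0, "live", np.zeros((140, 2), dtype=int), (0.0, 0.0),
                    np.zeros((1, 2)))
        ]
        once = filter_by_area(contours, 130)
        assert filter_by_area(once, 130) == once


def _contour_at(cid, cls, x, y, area=140):
    return Contour(cid, cls, np.zeros((area, 2), dtype=int), (x, y),
                   np.zeros((1, 2)))


class TestConflictResolution:
    def test_overlap_beats_live(self):
        live = [_contour_at(0, "live", 50.0, 50.0)]
        over = [_contour_at(0, "overlap", 52.0, 50.0)]
        out = resolve_class_conflicts([live, over], merge_radius=5.0)
        assert len(out) == 1
        assert out[0].class_label == "overlap"

    def test_distant_contours_both_kept(self):
        live = [_contour_at(0, "live", 10.0, 10.0)]
        dead = [_contour_at(0, "dead", 110.0, 10.0)]
        out = resolve_class_conflicts([live, dead], merge_radius=5.0)
        assert {c.class_label for c in out} == {"live", "dead"}

    def test_single_class_identity(self):
        live = [_contour_at(0, "live", 10.0, 10.0),
                _contour_at(1, "live", 60.0, 10.0)]
        out = resolve_class_conflicts([live], merge_radius=5.0)
        assert len(out) == 2

    def test_unique_ids_after_merge(self):
        sets = [[_contour_at(0, "live", 10.0, 10.0)],
                [_contour_at(0, "dead", 60.0, 10.0)],
                [_contour_at(0, "overlap", 12.0, 10.0)]]
        out = resolve_class_conflicts(sets, merge_radius=5.0)
        assert sorted(c.contour_id for c in out) == list(range(len(out)))


class TestLabelProjection:
    def test_labels_cover_mask_within_radius(self):
        mask = _disk_mask((30, 30), (15, 15), 8)
        labels = _disk_mask((30, 30), (15, 15), 7).astype(np.int32)
        out = project_labels_to_mask(labels, mask, radius=3.0)
        assert np.array_equal(out > 0, mask)

    def test_distant_speckle_dropped(self):
        mask = _disk_mask((30, 30), (15, 15), 5)
        mask[2, 2] = True  # isolated mask speckle far from any label
        labels = _disk_mask((30, 30), (15, 15), 5).astype(np.int32)
        out = project_labels_to_mask(labels, mask, radius=3.0)
        assert out[2, 2] == 0
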
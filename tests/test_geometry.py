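"""Tests of the resize and standardization transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvtrack import (
    AmbiguousApexError,
    CineSeries,
    DegeneratePlaneError,
    MVAnnotation,
    SimilarityTransform,
    apply_transform,
    estimate_standardization,
    map_points,
    resize_to_network_grid,
)
from mvtrack.core import STANDARD_SIZE
from mvtrack.geometry import crop_center


def make_cine(rows, cols, n_frames=3, spacing=(1.0, 1.0)):
    rng = np.random.default_rng(0)
    return CineSeries(rng.normal(0.5, 0.1, (n_frames, rows, cols)), spacing,
                      view="two_chamber")


transform_strategy = st.builds(
    SimilarityTransform.from_params,
    scale=st.tuples(st.floats(0.2, 5.0), st.floats(0.2, 5.0)),
    rotation_deg=st.floats(-360.0, 360.0),
    translation_px=st.tuples(st.floats(-200.0, 200.0), st.floats(-200.0, 200.0)),
    output_size=st.just((118, 162)),
)


class TestSimilarityTransform:
    @settings(max_examples=200, deadline=None)
    @given(transform_strategy, st.integers(0, 2**32 - 1))
    def test_forward_inverse_round_trip(self, transform, seed):
        pts = np.random.default_rng(seed).uniform(-300, 300, (50, 2))
        back = map_points(map_points(pts, transform, "forward"), transform, "inverse")
        assert np.abs(back - pts).max() < 1e-9

    def test_composition_equals_matrix_product(self):
        t1 = SimilarityTransform.from_params((2.0, 0.5), 0.0, (3.0, -1.0), (100, 100))
        t2 = SimilarityTransform.from_params((1.5, 1.5), 33.0, (-7.0, 2.0), (80, 90))
        composed = t2.compose(t1)
        pts = np.random.default_rng(1).uniform(-50, 50, (20, 2))
        direct = map_points(map_points(pts, t1), t2)
        assert np.abs(map_points(pts, composed) - direct).max() < 1e-9

    def test_json_round_trip(self):
        t = SimilarityTransform.from_params((1.3, 2.1), -42.0, (5.0, 6.0), (118, 162))
        t2 = SimilarityTransform.from_json(t.to_json())
        assert np.allclose(t2.matrix, t.matrix, atol=1e-12)
        assert np.allclose(t2.translation, t.translation, atol=1e-12)
        assert t2.output_size == t.output_size

    def test_identity_maps_points_unchanged(self):
        t = SimilarityTransform.identity((64, 64))
        pts = np.array([[1.5, 2.5], [10.0, 20.0]])
        assert np.array_equal(map_points(pts, t), pts)


class TestResize:
    def test_same_size_is_identity(self):
        cine = make_cine(160, 160)
        out, t = resize_to_network_grid(cine)
        assert np.array_equal(out.frames, cine.frames)
        assert np.allclose(t.matrix, np.eye(2))
        assert np.allclose(t.translation, 0.0)

    def test_halving_scale_maps_points(self):
        cine = make_cine(320, 320)
        out, t = resize_to_network_grid(cine, (160, 160))
        assert t.scale == pytest.approx((0.5, 0.5))
        assert map_points(np.array([100.0, 60.0]), t) == pytest.approx([50.0, 30.0])
        assert out.frames.shape == (3, 160, 160)
        assert out.pixel_spacing_mm == pytest.approx((2.0, 2.0))

    def test_anisotropic_round_trip(self):
        cine = make_cine(240, 160)
        _, t = resize_to_network_grid(cine, (160, 160))
        pts = np.random.default_rng(2).uniform(0, 150, (100, 2))
        back = map_points(map_points(pts, t), t, "inverse")
        assert np.abs(back - pts).max() < 1e-9

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            resize_to_network_grid(make_cine(1, 50))


def annotation_moving_down(p_left, p_right, n_frames=5, step=(0.0, 3.0)):
    """Frame-0 points plus later frames translated by ``step`` per frame."""
    pts = np.empty((n_frames, 2, 2))
    for i in range(n_frames):
        shift = np.asarray(step) * i
        pts[i, 0] = np.asarray(p_left) + shift
        pts[i, 1] = np.asarray(p_right) + shift
    return MVAnnotation(pts, ("anterior", "inferior"), "two_chamber")


class TestStandardization:
    def test_already_standard_gives_identity(self):
        c = crop_center()
        ann = annotation_moving_down(c - [10, 0], c + [10, 0], step=(0.0, 2.0))
        cine = make_cine(*STANDARD_SIZE, n_frames=5, spacing=(0.75, 0.75))
        t = estimate_standardization(ann, cine)
        assert np.allclose(t.matrix, np.eye(2), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    def test_scaling_and_centering_from_coarse_points(self):
        # 1.5 mm spacing -> scale 2.0; horizontal points, motion downward
        ann = annotation_moving_down((10.0, 10.0), (20.0, 10.0), step=(0.0, 2.0))
        cine = make_cine(100, 100, n_frames=5, spacing=(1.5, 1.5))
        t = estimate_standardization(ann, cine)
        assert t.scale == pytest.approx((2.0, 2.0))
        assert t.rotation_deg == pytest.approx(0.0)
        mid = map_points(np.array([15.0, 10.0]), t)
        assert mid == pytest.approx(crop_center(), abs=1e-9)

    @pytest.mark.parametrize("col_step", [+2.0, -2.0])
    def test_vertical_segment_rotated_so_motion_points_down(self, col_step):
        # vertical frame-0 segment; later midpoints drift along columns
        ann = annotation_moving_down((50.0, 40.0), (50.0, 60.0), step=(col_step, 0.0))
        cine = make_cine(100, 100, n_frames=5, spacing=(0.75, 0.75))
        t = estimate_standardization(ann, cine)
        assert abs(abs(t.rotation_deg) - 90.0) < 1e-9
        mapped_mids = map_points(ann.points.mean(axis=1), t)
        mv_row = map_points(ann.points[0], t)[:, 1].mean()
        assert np.all(mapped_mids[1:, 1] > mv_row)  # apex (motion) is below

    def test_frame0_horizontality_and_label_order(self, rotated_pair):
        cine, ann = rotated_pair
        t = estimate_standardization(ann, cine)
        mapped = map_points(ann.points[0], t)
        assert abs(mapped[0, 1] - mapped[1, 1]) < 1e-6  # horizontal
        assert mapped[0, 0] < mapped[1, 0]  # lateral point on the left
        mid = mapped.mean(axis=0)
        assert np.abs(mid - crop_center()).max() < 0.5
        # physical separation preserved by the 0.75 mm grid
        sep_px = np.linalg.norm(mapped[1] - mapped[0])
        sep_mm_orig = np.linalg.norm(
            (ann.points[0, 1] - ann.points[0, 0]) * cine.pixel_spacing_mm
        )
        assert sep_px * 0.75 == pytest.approx(sep_mm_orig, rel=1e-9)

    def test_degenerate_and_single_frame_errors(self):
        cine = make_cine(100, 100, n_frames=5)
        same = annotation_moving_down((10, 10), (10, 10))
        with pytest.raises(DegeneratePlaneError):
            estimate_standardization(same, cine)
        one = MVAnnotation(np.zeros((1, 2, 2)) + [[10, 10], [20, 10]],
                           ("anterior", "inferior"))
        with pytest.raises(AmbiguousApexError):
            estimate_standardization(one, cine)


class TestApplyTransform:
    def test_identity_on_standard_cine_is_pixel_identical(self):
        cine = make_cine(*STANDARD_SIZE, spacing=(0.75, 0.75))
        out = apply_transform(cine, SimilarityTransform.identity(STANDARD_SIZE))
        assert np.abs(out.cine.frames - cine.frames).max() < 1e-9

    def test_rotated_hot_pixel_lands_at_mapped_location(self):
        frames = np.zeros((1, *STANDARD_SIZE))
        src = np.array([100.0, 30.0])
        frames[0, int(src[1]), int(src[0])] = 1.0
        cine = CineSeries(frames, (0.75, 0.75))
        t = SimilarityTransform.from_params(
            (1.0, 1.0), 90.0, (0.0, 0.0), STANDARD_SIZE
        )
        # place the rotated point back in-frame via an extra translation
        dst = map_points(src, t)
        shift = np.array([40.0, 60.0]) - dst
        t = SimilarityTransform(t.matrix, t.translation + shift, STANDARD_SIZE)
        out = apply_transform(cine, t)
        peak = np.unravel_index(np.argmax(out.cine.frames[0]), STANDARD_SIZE)
        assert np.abs(np.array([peak[1], peak[0]]) - [40.0, 60.0]).max() <= 1.0

    def test_crop_outside_field_is_all_zero(self):
        cine = make_cine(50, 50)
        t = SimilarityTransform.from_params(
            (1.0, 1.0), 0.0, (5000.0, 5000.0), STANDARD_SIZE
        )
        out = apply_transform(cine, t)
        assert np.all(out.cine.frames == 0.0)

    def test_image_and_point_mapping_consistent(self, rotated_pair):
        """A marker painted at a ground-truth point appears at the mapped
        point after standardization (1 px tolerance)."""
        cine, ann = rotated_pair
        t = estimate_standardization(ann, cine)
        frames = np.zeros((1, *cine.shape))
        p = ann.points[0, 0]
        frames[0, int(round(p[1])), int(round(p[0]))] = 100.0
        marker = CineSeries(frames, cine.pixel_spacing_mm)
        out = apply_transform(marker, t)
        peak = np.unravel_index(np.argmax(out.cine.frames[0]), STANDARD_SIZE)
        mapped = map_points(np.round(p), t)
        assert np.abs(np.array([peak[1], peak[0]]) - mapped).max() <= 1.0
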
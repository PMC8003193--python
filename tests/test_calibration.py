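"""Scale calibration, centerline extraction, and rigid registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edgesharp import (AlignmentResult, Centerline, GridSearch, ScaledImage,
                       SceneSpec, align_by_centerlines, apply_alignment,
                       calibration_factor, extract_centerline, render_scene,
                       rescale_to_reference)
from edgesharp.calibration import _transform_points
from edgesharp.scene import _zigzag_vertices


class TestCalibrationFactor:
    def test_printed_microscope_scales(self):
        # OM at 0.212 um/px against SEM at 0.328 um/px
        assert calibration_factor(0.212, 0.328) == pytest.approx(
            0.6463414634146342, abs=1e-12)

    def test_identity_and_degenerate(self):
        assert calibration_factor(0.5, 0.5) == 1.0
        with pytest.raises(ValueError):
            calibration_factor(0.0, 0.3)
        with pytest.raises(ValueError):
            calibration_factor(0.3, -1.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_reciprocal_property(self, a, b):
        assert calibration_factor(a, b) * calibration_factor(b, a) == \
            pytest.approx(1.0, rel=1e-12)


class TestRescale:
    def test_equal_scales_is_identity(self, rng):
        img = ScaledImage(rng.integers(0, 255, (30, 40), dtype=np.uint8), 0.3)
        ref = ScaledImage(np.zeros((5, 5), np.uint8), 0.3)
        out = rescale_to_reference(img, ref)
        assert np.array_equal(out.pixels, img.pixels)
        assert out.scale == 0.3

    def test_half_factor_copies_source_pixels(self, rng):
        src = rng.integers(0, 255, (100, 100), dtype=np.uint8)
        om = ScaledImage(src, 0.164)
        sem = ScaledImage(np.zeros((5, 5), np.uint8), 0.328)
        out = rescale_to_reference(om, sem)
        assert out.shape == (50, 50)
        assert out.scale == 0.328
        # nearest-neighbor oracle: output (i, j) copies source (2i+1, 2j+1)
        ii, jj = np.mgrid[0:50, 0:50]
        assert np.array_equal(out.pixels, src[2 * ii + 1, 2 * jj + 1])

    def test_degenerate_output_rejected(self):
        om = ScaledImage(np.zeros((10, 10), np.uint8), 0.01)
        sem = ScaledImage(np.zeros((5, 5), np.uint8), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            rescale_to_reference(om, sem)


class TestCenterline:
    def test_straight_channel_midline(self):
        img = np.full((100, 120), 200, np.uint8)
        img[40:61, :] = 30  # dark lumen centered on row 50
        cl = extract_centerline(ScaledImage(img, 1.0), "two-level")
        mid = cl.points[(cl.points[:, 0] > 15) & (cl.points[:, 0] < 105)]
        assert np.abs(mid[:, 1] - 50).max() <= 1.0

    def test_blank_image_rejected(self):
        blank = ScaledImage(np.full((50, 50), 128, np.uint8), 1.0)
        for polarity in ("two-level", "dark-band"):
            with pytest.raises(ValueError):
                extract_centerline(blank, polarity)

    @pytest.mark.parametrize("angle", [30, 45, 60])
    def test_zigzag_vertex_angle_matches_spec(self, angle):
        spec = SceneSpec(image_height=400, image_width=400, channel_width=30,
                         wall_band_width=11, edge_offset=8,
                         turning_angle=angle, seed=1)
        pts = extract_centerline(render_scene(spec).sem_image,
                                 "two-level").points
        vx = _zigzag_vertices(spec)[:, 0]
        k = 30  # chord length: long enough to beat pixel quantization
        d = pts[k:] - pts[:-k]
        mid = (pts[k:] + pts[:-k]) / 2
        far = np.min(np.abs(mid[:, :1] - vx[None, :]), axis=1) > k / 2 + 10
        ang = np.degrees(np.arctan2(-d[far, 1], d[far, 0]))
        ang = (ang + 90) % 180 - 90  # fold out the path direction
        est = np.median(ang[ang > 1]) - np.median(ang[ang < -1])
        assert est == pytest.approx(angle, abs=2.0)

    def test_centerline_requires_two_points_and_bounded_steps(self):
        with pytest.raises(ValueError):
            Centerline(np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError, match="gap"):
            Centerline(np.array([[0.0, 0.0], [10.0, 0.0]]))


def _sine_centerline():
    t = np.linspace(0, 60, 150)
    return Centerline(np.column_stack([t + 30, 60 + 8 * np.sin(t / 6)]))


class TestAlign:
    def test_self_alignment_is_identity(self):
        ref = _sine_centerline()
        res = align_by_centerlines(ref, ref)
        assert res.score == pytest.approx(0.0, abs=1e-6)
        assert np.hypot(*res.translation) <= 0.1
        assert abs(res.rotation) <= 0.1

    def test_known_transform_recovery(self):
        ref = _sine_centerline()
        pivot = tuple(ref.points.mean(axis=0))
        moved = Centerline(_transform_points(ref.points, 7, -3, 2.0, pivot))
        res = align_by_centerlines(ref, moved, pivot=pivot)
        assert abs(res.rotation + 2.0) <= 0.25
        realigned = _transform_points(moved.points, *res.translation,
                                      res.rotation, pivot)
        assert np.hypot(*(realigned - ref.points).T).max() <= 0.5

    def test_returned_score_is_trace_minimum(self):
        ref = _sine_centerline()
        moved = Centerline(ref.points + (3.0, -1.0))
        res = align_by_centerlines(ref, moved)
        assert res.score == min(t[3] for t in res.trace)

    def test_single_point_sets(self):
        res = align_by_centerlines(np.array([[5.0, 5.0]]),
                                   np.array([[7.0, 5.0]]),
                                   GridSearch(max_shift=4, shift_step=1))
        assert res.score == pytest.approx(0.0, abs=1e-3)

    def test_empty_grid_rejected(self):
        ref = _sine_centerline()
        with pytest.raises(ValueError, match="empty search grid"):
            align_by_centerlines(ref, ref, GridSearch(max_shift=-2))


class TestApplyAlignment:
    def _img(self, rng):
        return ScaledImage(rng.integers(0, 255, (40, 40), dtype=np.uint8), 1.0)

    def test_identity_transform(self, rng):
        img = self._img(rng)
        res = AlignmentResult((0, 0), 0.0, 0.0, (19.5, 19.5), [])
        assert np.array_equal(apply_alignment(img, res).pixels, img.pixels)

    def test_translate_round_trip_on_interior(self, rng):
        img = self._img(rng)
        fwd = AlignmentResult((5, -3), 0.0, 0.0, (19.5, 19.5), [])
        back = AlignmentResult((-5, 3), 0.0, 0.0, (19.5, 19.5), [])
        rt = apply_alignment(apply_alignment(img, fwd), back)
        inner = (slice(8, 32), slice(8, 32))
        assert np.array_equal(rt.pixels[inner], img.pixels[inner])

    def test_quarter_turn_matches_direct_remap(self, rng):
        img = self._img(rng)
        res = AlignmentResult((0, 0), 90.0, 0.0, (19.5, 19.5), [])
        out = apply_alignment(img, res, fill=0).pixels
        oracle = np.zeros_like(img.pixels)
        for r in range(40):
            for c in range(40):
                x, y = c - 19.5, r - 19.5
                cc, rr = int(round(-y + 19.5)), int(round(x + 19.5))
                if 0 <= rr < 40 and 0 <= cc < 40:
                    oracle[rr, cc] = img.pixels[r, c]
        assert np.array_equal(out, oracle)
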
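"""Eye-anchored similarity alignment: closed-form solve and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catpain.alignment import (
    AlignmentConfig,
    SimilarityTransform,
    align_landmarks,
    apply_to_image,
    apply_to_landmarks,
    compute_transform,
    eye_centers,
)
from catpain.data_model import LandmarkSet
from catpain.errors import DegenerateGeometryError, ValidationError
from catpain.synthetic_data import render_face


def lstsq_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Independent two-point similarity solve: least-squares on [[a,-b],[b,a]],t.

    Unknowns (a, b, tx, ty) enter linearly: x' = a*x - b*y + tx,
    y' = b*x + a*y + ty.
    """
    rows, rhs = [], []
    for (x, y), (xp, yp) in zip(src, dst):
        rows.append([x, -y, 1.0, 0.0])
        rhs.append(xp)
        rows.append([y, x, 0.0, 1.0])
        rhs.append(yp)
    a, b, tx, ty = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
    return np.array([[a, -b, tx], [b, a, ty]])


def landmarks_with_eyes(left: tuple, right: tuple) -> LandmarkSet:
    """A landmark set whose eye-corner pairs collapse onto given eye centers."""
    coords = np.tile(np.array([250.0, 250.0]), (48, 1))
    coords[36] = coords[37] = left  # landmarks 37, 38
    coords[40] = coords[41] = right  # landmarks 41, 42
    return LandmarkSet(coords)


def random_similarity(rng: np.random.Generator) -> SimilarityTransform:
    return SimilarityTransform(
        angle=rng.uniform(-math.pi, math.pi),
        scale=rng.uniform(0.5, 2.0),
        translation=tuple(rng.uniform(-200, 200, size=2)),
    )


class TestEyeCenters:
    def test_midpoints(self):
        lms = landmarks_with_eyes((100, 200), (300, 210))
        coords = lms.coords.copy()
        coords[36] = (100, 200)
        coords[37] = (120, 220)
        left, right = eye_centers(LandmarkSet(coords))
        assert np.allclose(left, (110, 210))
        assert np.allclose(right, (300, 210))

    def test_template_centers_match_independent_midpoints(self, template):
        left, right = eye_centers(template)
        assert np.allclose(left, (template.point(37) + template.point(38)) / 2)
        assert np.allclose(right, (template.point(41) + template.point(42)) / 2)


class TestComputeTransform:
    def test_already_aligned_face_gets_identity(self):
        lms = landmarks_with_eyes((400, 400), (600, 400))
        t = compute_transform(lms)
        assert abs(t.angle) < 1e-12
        assert abs(t.scale - 1.0) < 1e-12
        assert np.allclose(t.translation, (0, 0), atol=1e-9)

    def test_diagonal_eye_line_matches_least_squares_oracle(self):
        lms = landmarks_with_eyes((100, 100), (200, 200))
        t = compute_transform(lms)
        assert np.isclose(t.scale, 200 / math.hypot(100, 100))  # = sqrt(2)
        oracle = lstsq_similarity(
            np.array([[100, 100], [200, 200]]), np.array([[400, 400], [600, 400]])
        )
        assert np.allclose(t.matrix, oracle, atol=1e-8)

    def test_coincident_eye_centers_degenerate(self):
        lms = landmarks_with_eyes((150, 150), (150, 150))
        with pytest.raises(DegenerateGeometryError):
            compute_transform(lms)

    def test_anchor_fraction_controls_targets(self, template):
        config = AlignmentConfig(out_width=800, out_height=600, eye_anchor_fraction=0.3)
        aligned = apply_to_landmarks(compute_transform(template, config), template)
        left, right = eye_centers(aligned)
        assert np.allclose(left, (0.3 * 800, 0.3 * 600), atol=1e-9)
        assert np.allclose(right, (0.7 * 800, 0.3 * 600), atol=1e-9)


class TestSimilarityTransform:
    def test_matrix_param_round_trip(self, rng):
        for _ in range(20):
            t = random_similarity(rng)
            back = SimilarityTransform.from_matrix(t.matrix)
            assert np.isclose(back.angle, t.angle)
            assert np.isclose(back.scale, t.scale)
            assert np.allclose(back.translation, t.translation)

    def test_from_matrix_rejects_shear(self):
        with pytest.raises(ValidationError):
            SimilarityTransform.from_matrix(np.array([[1.0, 0.3, 0.0], [0.0, 1.0, 0.0]]))

    def test_inverse_composes_to_identity(self, rng):
        t = random_similarity(rng)
        pts = rng.uniform(-100, 500, size=(10, 2))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_json_round_trip(self, rng):
        t = random_similarity(rng)
        back = SimilarityTransform.from_json(t.to_json())
        assert back == t

    def test_scale_must_be_positive(self):
        with pytest.raises(ValidationError):
            SimilarityTransform(angle=0.0, scale=0.0, translation=(0, 0))


class TestAlignmentInvariants:
    def test_identity_transform_leaves_landmarks(self, template):
        out = apply_to_landmarks(SimilarityTransform.identity(), template)
        assert np.array_equal(out.coords, template.coords)

    def test_left_eye_lands_on_anchor(self, template):
        aligned = align_landmarks(template)
        left, right = eye_centers(aligned)
        assert np.allclose(left, (400, 400), atol=1e-9)
        assert np.allclose(right, (600, 400), atol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        angle=st.floats(-math.pi, math.pi),
        scale=st.floats(0.2, 5.0),
        tx=st.floats(-300, 300),
        ty=st.floats(-300, 300),
    )
    def test_eye_line_horizontal_and_spacing_for_any_pose(self, angle, scale, tx, ty):
        from catpain.synthetic_data import make_template

        posed = apply_to_landmarks(
            SimilarityTransform(angle=angle, scale=scale, translation=(tx, ty)),
            make_template(),
        )
        aligned = align_landmarks(posed)
        left, right = eye_centers(aligned)
        assert abs(left[1] - right[1]) < 1e-6
        assert np.isclose(np.hypot(*(right - left)), 0.2 * 1000, atol=1e-6)

    def test_realignment_is_idempotent(self, template):
        aligned = align_landmarks(template)
        t = compute_transform(aligned)
        assert abs(t.angle) < 1e-6
        assert abs(t.scale - 1.0) < 1e-6
        assert np.allclose(t.translation, (0, 0), atol=1e-6)

    def test_distance_ratios_preserved(self, template, rng):
        t = random_similarity(rng)
        out = apply_to_landmarks(t, template)

        def ratio(lms):
            d1 = np.hypot(*(lms.point(1) - lms.point(17)))
            d2 = np.hypot(*(lms.point(27) - lms.point(34)))
            return d1 / d2

        assert np.isclose(ratio(out), ratio(template))


class TestApplyToImage:
    def test_output_frame_size(self, template):
        img = render_face(template)
        out = apply_to_image(compute_transform(template), img)
        assert out.shape == (1000, 1000)

    def test_identity_on_canonical_frame_is_noop(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(1000, 1000))
        out = apply_to_image(SimilarityTransform.identity(), img)
        assert np.allclose(out, img, atol=1e-9)

    def test_eye_dots_land_on_anchor_pixels(self, template):
        """Centroid-detection oracle: bright dots painted at the eye centers
        must come out centered within a pixel of the (400,400)/(600,400) anchors."""
        left, right = eye_centers(template)
        img = np.zeros((500, 500))
        for cx, cy in (left, right):
            yy, xx = np.mgrid[0:500, 0:500]
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 9] = 1.0
        out = apply_to_image(compute_transform(template), img)

        def centroid(region):
            yy, xx = np.nonzero(region)
            weights = region[yy, xx]
            return (
                np.average(xx, weights=weights),
                np.average(yy, weights=weights),
            )

        left_out = centroid(out[:, :500])
        right_out_x, right_out_y = centroid(out[:, 500:])
        assert np.allclose(left_out, (400, 400), atol=1.0)
        assert np.allclose((right_out_x + 500, right_out_y), (600, 400), atol=1.0)
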
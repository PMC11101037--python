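import numpy as np
import pytest

from crmkit import geometry, io
from crmkit.errors import FitError, GeometryError, StructureError
from crmkit.geometry import (
    AFFINE_ANCHORS,
    MIRROR_PAIRS,
    ReferenceFace,
    RegistrationConfig,
    affine_register,
    compute_kpm,
    fit_affine,
    fit_similarity,
    frontalize,
    partwise_similarity_register,
    preprocess_cohort,
)

from conftest import make_recording


def rot(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


class TestFitAffine:
    def test_identity(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 3.0]])
        tf = fit_affine(src, src)
        np.testing.assert_allclose(tf.A, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tf.b, 0, atol=1e-12)

    def test_hand_solved_three_pairs(self):
        # (0,0)->(1,2), (1,0)->(3,2), (0,1)->(1,5): A=[[2,0],[0,3]], b=(1,2)
        src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        dst = np.array([[1.0, 2.0], [3.0, 2.0], [1.0, 5.0]])
        tf = fit_affine(src, dst)
        np.testing.assert_allclose(tf.A, [[2.0, 0.0], [0.0, 3.0]], atol=1e-10)
        np.testing.assert_allclose(tf.b, [1.0, 2.0], atol=1e-10)

    def test_collinear_src_raises(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(FitError, match="collinear"):
            fit_affine(src, src + 1)

    def test_least_squares_recovers_exact_map(self, rng):
        src = rng.uniform(-5, 5, (10, 2))
        A = np.array([[1.3, -0.4], [0.2, 0.9]])
        b = np.array([2.0, -1.0])
        tf = fit_affine(src, src @ A.T + b)
        np.testing.assert_allclose(tf.A, A, atol=1e-9)
        np.testing.assert_allclose(tf.b, b, atol=1e-9)


class TestFitSimilarity:
    def test_identity(self):
        src = np.array([[0.0, 0.0], [1.0, 2.0]])
        tf = fit_similarity(src, src)
        assert tf.scale == pytest.approx(1.0)
        assert tf.rotation == pytest.approx(0.0)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-12)

    def test_two_point_scale_rotation(self):
        # (0,0),(1,0) -> (0,0),(0,2): scale 2, +90 degrees, zero translation
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        dst = np.array([[0.0, 0.0], [0.0, 2.0]])
        tf = fit_similarity(src, dst)
        assert tf.scale == pytest.approx(2.0)
        assert tf.rotation == pytest.approx(np.pi / 2)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-12)

    def test_single_pair_translation_only(self):
        tf = fit_similarity([[1.0, 1.0]], [[4.0, 5.0]])
        assert tf.scale == 1.0 and tf.rotation == 0.0
        np.testing.assert_allclose(tf.translation, [3.0, 4.0])

    def test_coincident_src_raises(self):
        src = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(FitError, match="degenerate"):
            fit_similarity(src, np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestFrontalize:
    def test_symmetric_level_face_fixed_point(self, static_recording):
        out = frontalize(static_recording)
        np.testing.assert_allclose(out.coords, static_recording.coords,
                                   atol=1e-9)

    def test_inverts_known_rotation(self, template_face):
        center = (template_face[36] + template_face[45]) / 2
        rotated = (template_face - center) @ rot(10).T + center
        rec = make_recording(rotated[None])
        out = frontalize(rec)
        np.testing.assert_allclose(out.coords[0], template_face, atol=1e-9)

    def test_none_is_identity(self, rng):
        rec = make_recording(rng.uniform(0, 512, (2, 66, 2)))
        out = frontalize(rec, method="none")
        np.testing.assert_array_equal(out.coords, rec.coords)

    def test_degenerate_eye_axis(self, template_face):
        pts = template_face.copy()
        pts[45] = pts[36]
        with pytest.raises(GeometryError, match="eye axis"):
            frontalize(make_recording(pts[None]))

    def test_unknown_method(self, static_recording):
        with pytest.raises(GeometryError):
            frontalize(static_recording, method="3d")

    def test_output_is_symmetric(self, rng, template_face):
        noisy = template_face + rng.normal(0, 2, (66, 2))
        out = frontalize(make_recording(noisy[None])).coords[0]
        x0 = out[27, 0]
        for left, right in MIRROR_PAIRS:
            assert out[left, 0] - x0 == pytest.approx(-(out[right, 0] - x0),
                                                      abs=1e-9)
            assert out[left, 1] == pytest.approx(out[right, 1], abs=1e-9)


class TestAffineRegister:
    def test_anchor_match_leaves_anchors(self, template_face):
        ref = ReferenceFace(template_face)
        rec = make_recording(template_face[None].repeat(2, axis=0))
        out = affine_register(rec, ref)
        expected = np.repeat(template_face[list(AFFINE_ANCHORS)][None], 2, axis=0)
        np.testing.assert_allclose(
            out.coords[:, list(AFFINE_ANCHORS)], expected, atol=1e-9
        )

    def test_recovers_known_affine_distortion(self, template_face, rng):
        ref = ReferenceFace(template_face)
        frames = []
        for _ in range(3):
            A = np.eye(2) + rng.normal(0, 0.1, (2, 2))
            b = rng.normal(0, 20, 2)
            frames.append(template_face @ A.T + b)
        out = affine_register(make_recording(np.stack(frames)), ref)
        np.testing.assert_allclose(
            out.coords, template_face[None].repeat(3, axis=0), atol=1e-6
        )

    def test_idempotent(self, template_face, rng):
        ref = ReferenceFace(template_face)
        rec = make_recording(
            (template_face + rng.normal(0, 3, (66, 2)))[None]
        )
        once = affine_register(rec, ref)
        twice = affine_register(once, ref)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_singular_frame_reports_index(self, template_face):
        ref = ReferenceFace(template_face)
        pts = template_face.copy()
        pts[list(AFFINE_ANCHORS)] = [[0, 0], [1, 1], [2, 2], [3, 3], [4, 4],
                                     [5, 5]]
        with pytest.raises(FitError, match="frame 0"):
            affine_register(make_recording(pts[None]), ref)


class TestPartwiseSimilarity:
    def test_reference_frame_unchanged(self, template_face):
        ref = ReferenceFace(template_face)
        out = partwise_similarity_register(
            make_recording(template_face[None]), ref
        )
        np.testing.assert_allclose(out.coords[0], template_face, atol=1e-9)

    def test_scaled_eye_restored(self, template_face):
        # scale the left brow+eye block x1.5 about its anchor midpoint
        ref = ReferenceFace(template_face)
        part = geometry.DEFAULT_PART_MAP["left_brow_eye"]
        pts = template_face.copy()
        mid = (pts[42] + pts[45]) / 2
        idx = list(part.members)
        pts[idx] = (pts[idx] - mid) * 1.5 + mid
        out = partwise_similarity_register(make_recording(pts[None]), ref)
        np.testing.assert_allclose(out.coords[0, idx], template_face[idx],
                                   atol=1e-9)

    def test_lips_never_move(self, template_face, rng):
        ref = ReferenceFace(template_face)
        pts = template_face + rng.normal(0, 3, (66, 2))
        pts[48:66] += rng.uniform(-40, 40, 2)  # arbitrary lip translation
        out = partwise_similarity_register(make_recording(pts[None]), ref)
        np.testing.assert_array_equal(out.coords[0, 48:66], pts[48:66])

    def test_nose_translation_only(self, template_face):
        ref = ReferenceFace(template_face)
        pts = template_face.copy()
        pts[27:36] += np.array([7.0, -3.0])
        out = partwise_similarity_register(make_recording(pts[None]), ref)
        np.testing.assert_allclose(out.coords[0, 27:36], template_face[27:36],
                                   atol=1e-9)


class TestComputeKPM:
    def test_neutral_frame_is_zero(self, rng):
        rec = make_recording(rng.uniform(0, 100, (4, 66, 2)))
        kpm = compute_kpm(rec, neutral_frame_index=2)
        np.testing.assert_array_equal(kpm.values[2], np.zeros(132))

    def test_uniform_shift(self, template_face):
        frames = np.stack([template_face, template_face + [1.0, 2.0]])
        kpm = compute_kpm(make_recording(frames), 0)
        np.testing.assert_allclose(kpm.values[1, :66], 1.0)
        np.testing.assert_allclose(kpm.values[1, 66:], 2.0)

    def test_linearity_midpoint(self, rng, template_face):
        f1 = template_face + rng.normal(0, 3, (66, 2))
        f2 = template_face + rng.normal(0, 3, (66, 2))
        mid = (f1 + f2) / 2
        kpm = compute_kpm(make_recording(np.stack([template_face, f1, f2, mid])))
        np.testing.assert_allclose(
            kpm.values[3], (kpm.values[1] + kpm.values[2]) / 2, atol=1e-9
        )

    def test_out_of_range_neutral(self, static_recording):
        with pytest.raises(StructureError):
            compute_kpm(static_recording, neutral_frame_index=99)


class TestPreprocessCohort:
    def test_static_cohort_zero_kpm(self, static_cohort):
        result = preprocess_cohort(static_cohort)
        for series in result.kpm:
            np.testing.assert_allclose(series.values, 0, atol=1e-9)

    def test_per_subject_global_affine_removed(self, template_face, rng):
        base = np.repeat(template_face[None], 3, axis=0)
        base[1, 48:66, 1] += 5.0  # a lip motion signal
        recs = []
        for i in range(3):
            A = np.eye(2) + rng.normal(0, 0.05, (2, 2))
            b = rng.normal(0, 10, 2)
            recs.append(make_recording(base @ A.T + b, f"s{i}"))
        cohort = io.CohortDataset(recs)
        # general affines (with shear) do not commute with symmetrization,
        # so the pure registration path is exercised here
        config = RegistrationConfig(
            frontalization="none", reference=ReferenceFace(template_face)
        )
        result = preprocess_cohort(cohort, config)
        # nuisance affines removed: all subjects agree despite different A, b
        for series in result.kpm[1:]:
            np.testing.assert_allclose(
                series.values, result.kpm[0].values, atol=1e-6
            )

    def test_registration_invariance_per_frame_affine(self, template_face, rng):
        base = np.repeat(template_face[None], 4, axis=0)
        base += rng.normal(0, 1.5, base.shape)
        config = RegistrationConfig(
            frontalization="none", reference=ReferenceFace(template_face)
        )
        recs = [make_recording(base + i, f"s{i}") for i in range(3)]
        plain = preprocess_cohort(io.CohortDataset(recs), config)
        distorted = []
        for rec in recs:
            frames = np.empty_like(rec.coords)
            for t in range(rec.n_frames):
                A = np.eye(2) + rng.normal(0, 0.08, (2, 2))
                b = rng.normal(0, 15, 2)
                frames[t] = rec.coords[t] @ A.T + b
            distorted.append(make_recording(frames, rec.subject_id))
        warped = preprocess_cohort(io.CohortDataset(distorted), config)
        for a, b_ in zip(plain.kpm, warped.kpm):
            np.testing.assert_allclose(a.values, b_.values, atol=1e-6)

    def test_similarity_nuisance_invariant_with_frontalization(
        self, template_face, rng
    ):
        base = np.repeat(template_face[None], 4, axis=0)
        base += rng.normal(0, 1.0, base.shape)
        config = RegistrationConfig(reference=ReferenceFace(template_face))
        recs = [make_recording(base + i, f"s{i}") for i in range(3)]
        plain = preprocess_cohort(io.CohortDataset(recs), config)
        distorted = []
        for rec in recs:
            frames = np.empty_like(rec.coords)
            for t in range(rec.n_frames):
                a = rng.uniform(-np.pi / 12, np.pi / 12)
                s = rng.uniform(0.8, 1.2)
                R = s * np.array([[np.cos(a), -np.sin(a)],
                                  [np.sin(a), np.cos(a)]])
                frames[t] = rec.coords[t] @ R.T + rng.uniform(-30, 30, 2)
            distorted.append(make_recording(frames, rec.subject_id))
        warped = preprocess_cohort(io.CohortDataset(distorted), config)
        for a_, b_ in zip(plain.kpm, warped.kpm):
            np.testing.assert_allclose(a_.values, b_.values, atol=1e-6)

    def test_neutral_rules(self, template_face):
        frames = np.repeat(template_face[None], 5, axis=0)
        frames[0] += 30.0  # outlier frame; median-closest is any other
        rec = make_recording(frames)
        assert geometry.resolve_neutral_index(rec, "first") == 0
        assert geometry.resolve_neutral_index(rec, 3) == 3
        assert geometry.resolve_neutral_index(rec, "auto") != 0
        with pytest.raises(StructureError):
            geometry.resolve_neutral_index(rec, "median")

    def test_stage_order_matters(self, template_face, rng):
        # swapping affine and part-wise stages changes output on a
        # distorted fixture: part-wise fits are not affine-equivariant
        ref = ReferenceFace(template_face)
        pts = template_face.copy()
        A = np.array([[1.2, 0.3], [-0.1, 0.8]])
        pts = pts @ A.T + [11.0, -7.0]
        part = geometry.DEFAULT_PART_MAP["left_brow_eye"]
        idx = list(part.members)
        mid = (pts[42] + pts[45]) / 2
        pts[idx] = (pts[idx] - mid) * 1.3 + mid
        rec = make_recording(pts[None])
        in_order = partwise_similarity_register(
            affine_register(rec, ref), ref
        ).coords
        swapped = affine_register(
            partwise_similarity_register(rec, ref), ref
        ).coords
        assert np.abs(in_order - swapped).max() > 1e-3


def test_reference_face_rejects_collinear_anchors():
    pts = np.zeros((66, 2))
    pts[:, 0] = np.arange(66)
    pts[:, 1] = np.arange(66) * 2.0
    with pytest.raises(GeometryError):
        ReferenceFace(pts)


def test_mirror_pairs_partition():
    seen = [i for pair in MIRROR_PAIRS for i in pair]
    assert len(seen) == len(set(seen))
    assert set(seen) | set(geometry.MIDLINE_POINTS) == set(range(66))
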
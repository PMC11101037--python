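"""Geometric normalization of facial keypoints and movement vectors.

The preprocessing pipeline removes nuisance variation in three stages:

1. frontalization (in-plane roll correction + bilateral symmetrization),
2. whole-face affine registration to a shared reference via six anchors,
3. part-wise similarity registration (brow+eye blocks, nose, jawline);
   lips have no fixed anchors and are left untouched by stage 3.

After registration, per-frame movement is expressed as a 132-vector of
coordinate differences from the subject's neutral frame (x block then
y block).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FitError, GeometryError, StructureError
from .io import KPM_DIM, N_KEYPOINTS, CohortDataset, SubjectRecording

#: Anchors used for whole-face affine registration.
AFFINE_ANCHORS: tuple[int, ...] = (0, 16, 39, 42, 27, 33)

#: Outer eye-corner indices defining the roll axis.
RIGHT_EYE_OUTER, LEFT_EYE_OUTER = 36, 45

#: Left/right mirror pairing of the 66-point layout (lower index on the
#: subject's right, i.e. lower x in a frontal image-convention view).
MIRROR_PAIRS: tuple[tuple[int, int], ...] = (
    # jawline
    (0, 16), (1, 15), (2, 14), (3, 13), (4, 12), (5, 11), (6, 10), (7, 9),
    # brows
    (17, 26), (18, 25), (19, 24), (20, 23), (21, 22),
    # nostril row
    (31, 35), (32, 34),
    # eyes
    (36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46),
    # outer lips
    (48, 54), (49, 53), (50, 52), (55, 59), (56, 58),
    # inner lips
    (60, 62), (63, 65),
)

#: Keypoints lying on the facial midline.
MIDLINE_POINTS: tuple[int, ...] = (8, 27, 28, 29, 30, 33, 51, 57, 61, 64)


@dataclass(frozen=True)
class AffineTransform:
    """Six-parameter planar affine map p -> A @ p + b."""

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.A.shape != (2, 2) or self.b.shape != (2,):
            raise FitError("affine transform needs a 2x2 A and a 2-vector b")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.A))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.A.T + self.b


@dataclass(frozen=True)
class SimilarityTransform:
    """Four-parameter map p -> s * R(theta) @ p + t (s > 0)."""

    scale: float
    rotation: float  # radians
    translation: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise FitError(f"similarity scale must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, np.zeros(2))

    def as_affine(self) -> AffineTransform:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        A = self.scale * np.array([[c, -s], [s, c]])
        return AffineTransform(A, self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.as_affine().apply(points)


@dataclass(frozen=True)
class FacePart:
    members: tuple[int, ...]
    anchors: tuple[int, ...]


#: Default part map for part-wise similarity registration.  Anchor choices:
#: 42/45 for the left brow+eye block, 36/39 for the right, 27 for the nose
#: (translation-only), 0/16 for the jawline; lips have no fixed anchors.
DEFAULT_PART_MAP: dict[str, FacePart] = {
    "right_brow_eye": FacePart(tuple(range(17, 22)) + tuple(range(36, 42)), (36, 39)),
    "left_brow_eye": FacePart(tuple(range(22, 27)) + tuple(range(42, 48)), (42, 45)),
    "nose": FacePart(tuple(range(27, 36)), (27,)),
    "jawline": FacePart(tuple(range(0, 17)), (0, 16)),
    "lips": FacePart(tuple(range(48, 66)), ()),
}


def _validate_part_map(parts: Mapping[str, FacePart]) -> None:
    seen: set[int] = set()
    for name, part in parts.items():
        members = set(part.members)
        if seen & members:
            raise StructureError(f"part {name!r} overlaps another part")
        seen |= members
        if not members <= set(range(N_KEYPOINTS)):
            raise StructureError(f"part {name!r} has out-of-range members")


@dataclass(frozen=True)
class ReferenceFace:
    """Canonical 66-point face used as the registration target."""

    points: np.ndarray  # (66, 2)
    provenance: str = "supplied"  # "cohort-mean" | "supplied"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_KEYPOINTS, 2):
            raise StructureError(f"reference face must be (66, 2), got {pts.shape}")
        object.__setattr__(self, "points", pts)
        anchors = pts[list(AFFINE_ANCHORS)]
        if _collinear(anchors):
            raise GeometryError("reference affine anchors are collinear")


@dataclass
class KPMSeries:
    """Per-frame 132-dim movement vectors relative to a neutral frame."""

    subject_id: str
    values: np.ndarray  # (T, 132)
    neutral_frame_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != KPM_DIM:
            raise StructureError(
                f"KPM values must be (T, {KPM_DIM}), got {self.values.shape}"
            )
        if not 0 <= self.neutral_frame_index < self.values.shape[0]:
            raise StructureError("neutral frame index out of range")
        if np.any(self.values[self.neutral_frame_index] != 0):
            raise StructureError(
                "movement at the neutral frame must be exactly zero"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    if len(pts) < 3:
        return True
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    return s[1] / scale < tol


# ---------------------------------------------------------------------------
# transform fitting
# ---------------------------------------------------------------------------


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares six-parameter affine mapping ``src`` onto ``dst``.

    Exact for three non-collinear pairs; raises :class:`FitError` when the
    source points are (near-)collinear.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise FitError("src and dst must be matching (N, 2) arrays")
    if len(src) < 3:
        raise FitError("affine fit needs at least 3 point pairs")
    if _collinear(src):
        raise FitError("affine fit is singular: source points are collinear")
    design = np.hstack([src, np.ones((len(src), 1))])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    A = sol[:2].T
    b = sol[2]
    if abs(np.linalg.det(A)) < 1e-12:
        raise FitError("affine fit produced a singular linear part")
    return AffineTransform(A, b)


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares four-parameter similarity mapping ``src`` onto ``dst``.

    Solved in the complex plane: dst ~ a*src + b with a = s*exp(i*theta).
    A single pair is under-determined and fixed by convention to pure
    translation (s=1, theta=0).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise FitError("src and dst must be matching (N, 2) arrays")
    if len(src) == 0:
        raise FitError("similarity fit needs at least 1 point pair")
    if len(src) == 1:
        return SimilarityTransform(1.0, 0.0, dst[0] - src[0])
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    if np.allclose(z, z[0], atol=1e-12):
        raise FitError("similarity fit degenerate: source points coincide")
    design = np.stack([z, np.ones_like(z)], axis=1)
    (a, b), *_ = np.linalg.lstsq(design, w, rcond=None)
    scale = abs(a)
    if scale < 1e-12:
        raise FitError("similarity fit collapsed to zero scale")
    return SimilarityTransform(
        float(scale), float(np.angle(a)), np.array([b.real, b.imag])
    )


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _frontalize_frame(pts: np.ndarray) -> np.ndarray:
    e1, e2 = pts[RIGHT_EYE_OUTER], pts[LEFT_EYE_OUTER]
    axis = e2 - e1
    norm = np.hypot(*axis)
    if norm < 1e-12:
        raise GeometryError("degenerate eye axis: outer eye corners coincide")
    theta = np.arctan2(axis[1], axis[0])
    c, s = np.cos(-theta), np.sin(-theta)
    R = np.array([[c, -s], [s, c]])
    center = (e1 + e2) / 2.0
    out = (pts - center) @ R.T + center
    # bilateral symmetrization about the vertical midline through the nose
    x0 = out[27, 0]
    sym = out.copy()
    for left, right in MIRROR_PAIRS:
        p_l, p_r = out[left], out[right]
        mirrored_r = np.array([2 * x0 - p_r[0], p_r[1]])
        new_l = (p_l + mirrored_r) / 2.0
        sym[left] = new_l
        sym[right] = np.array([2 * x0 - new_l[0], new_l[1]])
    sym[list(MIDLINE_POINTS), 0] = x0
    return sym


def frontalize(recording: SubjectRecording, method: str = "roll_symmetrize") -> SubjectRecording:
    """Approximate a front-facing view of each frame.

    ``roll_symmetrize`` (default) removes in-plane roll using the outer
    eye-corner axis and then averages each keypoint with the reflection of
    its contralateral partner about the vertical midline through the nose
    bridge; midline points are projected onto the midline.  ``none`` is an
    identity pass-through for already-frontal data.
    """
    if method == "none":
        return recording.with_coords(recording.coords.copy())
    if method != "roll_symmetrize":
        raise GeometryError(f"unknown frontalization method {method!r}")
    out = np.empty_like(recording.coords)
    for t in range(recording.n_frames):
        try:
            out[t] = _frontalize_frame(recording.coords[t])
        except GeometryError as exc:
            raise GeometryError(
                f"subject {recording.subject_id!r}, frame {t}: {exc}"
            ) from exc
    return recording.with_coords(out)


def affine_register(
    recording: SubjectRecording,
    reference: ReferenceFace,
    anchors: Sequence[int] = AFFINE_ANCHORS,
) -> SubjectRecording:
    """Register every frame to the reference via its six-anchor affine fit."""
    idx = list(anchors)
    ref_pts = reference.points[idx]
    out = np.empty_like(recording.coords)
    for t in range(recording.n_frames):
        try:
            tf = fit_affine(recording.coords[t, idx], ref_pts)
        except FitError as exc:
            raise FitError(
                f"subject {recording.subject_id!r}, frame {t}: {exc}"
            ) from exc
        out[t] = tf.apply(recording.coords[t])
    return recording.with_coords(out)


def partwise_similarity_register(
    recording: SubjectRecording,
    reference: ReferenceFace,
    parts: Mapping[str, FacePart] | None = None,
) -> SubjectRecording:
    """Per-part similarity registration; parts without anchors stay put."""
    parts = DEFAULT_PART_MAP if parts is None else dict(parts)
    _validate_part_map(parts)
    out = recording.coords.copy()
    for name, part in parts.items():
        if not part.anchors:
            continue
        a_idx = list(part.anchors)
        m_idx = list(part.members)
        ref_pts = reference.points[a_idx]
        for t in range(recording.n_frames):
            try:
                tf = fit_similarity(recording.coords[t, a_idx], ref_pts)
            except FitError as exc:
                raise FitError(
                    f"subject {recording.subject_id!r}, part {name!r}, "
                    f"frame {t}: {exc}"
                ) from exc
            out[t, m_idx] = tf.apply(recording.coords[t, m_idx])
    return recording.with_coords(out)


def compute_kpm(recording: SubjectRecording, neutral_frame_index: int = 0) -> KPMSeries:
    """Movement vectors X(t) = coords(t) - coords(neutral), packed [dx | dy]."""
    if not 0 <= neutral_frame_index < recording.n_frames:
        raise StructureError(
            f"neutral frame index {neutral_frame_index} out of range "
            f"[0, {recording.n_frames})"
        )
    delta = recording.coords - recording.coords[neutral_frame_index]
    values = np.concatenate([delta[:, :, 0], delta[:, :, 1]], axis=1)
    return KPMSeries(recording.subject_id, values, neutral_frame_index)


# ---------------------------------------------------------------------------
# cohort preprocessing
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Options controlling the full preprocessing pipeline."""

    frontalization: str = "roll_symmetrize"
    neutral: int | str | Mapping[str, int] = "first"  # "first" | "auto" | int | map
    anchors: tuple[int, ...] = AFFINE_ANCHORS
    parts: Mapping[str, FacePart] | None = None
    reference: ReferenceFace | None = None

    def to_dict(self) -> dict:
        return {
            "frontalization": self.frontalization,
            "neutral": self.neutral if not isinstance(self.neutral, Mapping)
            else dict(self.neutral),
            "anchors": list(self.anchors),
            "parts": "default" if self.parts is None else sorted(self.parts),
            "reference": None if self.reference is None
            else self.reference.provenance,
        }


def resolve_neutral_index(
    recording: SubjectRecording, rule: int | str | Mapping[str, int]
) -> int:
    """Turn a neutral-frame rule into a concrete frame index."""
    if isinstance(rule, Mapping):
        rule = rule[recording.subject_id]
    if isinstance(rule, (int, np.integer)):
        idx = int(rule)
    elif rule == "first":
        idx = 0
    elif rule == "auto":
        median = np.median(recording.coords, axis=0)
        dist = np.linalg.norm(recording.coords - median, axis=2).mean(axis=1)
        idx = int(np.argmin(dist))
    else:
        raise StructureError(f"unknown neutral-frame rule {rule!r}")
    if not 0 <= idx < recording.n_frames:
        raise StructureError(f"neutral frame {idx} out of range")
    return idx


@dataclass
class PreprocessResult:
    kpm: list[KPMSeries]
    reference: ReferenceFace
    neutral_indices: dict[str, int]
    registered: list[SubjectRecording] = field(default_factory=list, repr=False)


def preprocess_cohort(
    cohort: CohortDataset,
    config: RegistrationConfig | None = None,
    keep_registered: bool = False,
) -> PreprocessResult:
    """Run frontalize -> affine -> part-wise similarity -> KPM per subject.

    The shared registration target defaults to the cohort mean of the
    frontalized neutral frames; a fixed reference may be supplied instead.
    """
    config = config or RegistrationConfig()
    fronted: list[SubjectRecording] = []
    neutral_indices: dict[str, int] = {}
    for rec in cohort.recordings:
        neutral_indices[rec.subject_id] = resolve_neutral_index(rec, config.neutral)
        fronted.append(frontalize(rec, config.frontalization))
    if config.reference is not None:
        reference = config.reference
    else:
        neutrals = np.stack(
            [f.coords[neutral_indices[f.subject_id]] for f in fronted]
        )
        reference = ReferenceFace(neutrals.mean(axis=0), provenance="cohort-mean")
    kpm: list[KPMSeries] = []
    registered: list[SubjectRecording] = []
    for rec in fronted:
        reg = affine_register(rec, reference, config.anchors)
        reg = partwise_similarity_register(reg, reference, config.parts)
        kpm.append(compute_kpm(reg, neutral_indices[rec.subject_id]))
        if keep_registered:
            registered.append(reg)
    return PreprocessResult(kpm, reference, neutral_indices, registered)
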
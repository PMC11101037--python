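"""Synthetic cohorts of facial-keypoint trajectories with known ground truth.

Generation per subject: a canonical symmetric 66-point template, deformed
by a small per-subject shape affine, plus epochs of coherent AU-like
displacement (each subject participates in an epoch with probability p,
with a per-subject amplitude and a trapezoidal onset/apex/offset ramp),
plus i.i.d. Gaussian positional jitter, optionally followed by a per-frame
in-plane head-pose nuisance transform.  AU intensity labels (0-5) are
quantized from the per-frame displacement amplitude, so the emitted labels
and the generator's participation ground truth agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError
from .io import (
    AU_IDS,
    KPM_DIM,
    N_KEYPOINTS,
    AULabelSequence,
    CohortDataset,
    Segment,
    SegmentTable,
    SubjectRecording,
)

# ---------------------------------------------------------------------------
# canonical face template (symmetric about x = 256 in a 512 x 512 frame)
# ---------------------------------------------------------------------------


def _build_template() -> np.ndarray:
    pts = np.zeros((N_KEYPOINTS, 2))
    # jawline 0-16: half ellipse, chin at index 8
    theta = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = -80.0 * np.cos(theta)
    pts[0:17, 1] = -10.0 + 100.0 * np.sin(theta)
    # brows 17-26
    brow_x = np.array([-65.0, -52.5, -40.0, -27.5, -15.0])
    brow_y = np.array([-45.0, -50.0, -52.0, -50.0, -46.0])
    pts[17:22] = np.stack([brow_x, brow_y], axis=1)
    pts[22:27] = np.stack([-brow_x[::-1], brow_y[::-1]], axis=1)
    # nose bridge 27-30 and nostril row 31-35
    pts[27:31] = [[0.0, -35.0], [0.0, -20.0], [0.0, -5.0], [0.0, 10.0]]
    pts[31:36] = [[-12.0, 18.0], [-6.0, 20.0], [0.0, 21.0],
                  [6.0, 20.0], [12.0, 18.0]]
    # eyes 36-47
    pts[36:42] = [[-55.0, -25.0], [-45.0, -30.0], [-35.0, -30.0],
                  [-25.0, -25.0], [-35.0, -20.0], [-45.0, -20.0]]
    pts[42:48] = [[25.0, -25.0], [35.0, -30.0], [45.0, -30.0],
                  [55.0, -25.0], [45.0, -20.0], [35.0, -20.0]]
    # outer lips 48-59
    pts[48:60] = [[-30.0, 45.0], [-20.0, 38.0], [-8.0, 35.0], [0.0, 36.0],
                  [8.0, 35.0], [20.0, 38.0], [30.0, 45.0], [20.0, 55.0],
                  [8.0, 60.0], [0.0, 61.0], [-8.0, 60.0], [-20.0, 55.0]]
    # inner lips 60-65
    pts[60:66] = [[-18.0, 45.0], [0.0, 44.0], [18.0, 45.0],
                  [18.0, 49.0], [0.0, 50.0], [-18.0, 49.0]]
    return pts + np.array([256.0, 256.0])


#: Canonical neutral face, (66, 2), bilaterally symmetric.
FACE_TEMPLATE: np.ndarray = _build_template()


def _field(displacements: dict[int, tuple[float, float]]) -> np.ndarray:
    """Pack a sparse keypoint displacement map into a unit 132-vector."""
    v = np.zeros(KPM_DIM)
    for idx, (dx, dy) in displacements.items():
        v[idx] = dx
        v[N_KEYPOINTS + idx] = dy
    norm = np.linalg.norm(v)
    if norm == 0:
        raise StructureError("empty displacement field")
    return v / norm


#: Unit displacement field per AU (image convention: y grows downward, so
#: an upward pull is negative dy).
AU_PATTERNS: dict[int, np.ndarray] = {
    # inner brows pulled upwards
    1: _field({20: (0, -1), 21: (0, -1), 22: (0, -1), 23: (0, -1)}),
    # outer brows pulled upwards
    2: _field({17: (0, -1), 18: (0, -1), 25: (0, -1), 26: (0, -1)}),
    # brows pulled downwards
    4: _field({i: (0, 1) for i in range(17, 27)}),
    # upper eyelids raised
    5: _field({37: (0, -1), 38: (0, -1), 43: (0, -1), 44: (0, -1)}),
    # cheeks pulled towards eyes (lower lids rise)
    6: _field({40: (0, -1), 41: (0, -1), 46: (0, -1), 47: (0, -1)}),
    # skin around nose pulled towards nasal root
    9: _field({30: (0, -1), 31: (0, -1), 32: (0, -1), 33: (0, -1),
               34: (0, -1), 35: (0, -1)}),
    # lip corners pulled obliquely upwards
    12: _field({48: (-1, -1), 54: (1, -1)}),
    # lip corners pulled down
    15: _field({48: (0, 1), 54: (0, 1)}),
    # lower lip and chin pushed upward
    17: _field({56: (0, -1), 57: (0, -1), 58: (0, -1),
                7: (0, -1), 8: (0, -1), 9: (0, -1)}),
    # lip corners stretched horizontally outwards
    20: _field({48: (-1, 0), 49: (-0.5, 0), 53: (0.5, 0), 54: (1, 0)}),
    # lips part
    25: _field({50: (0, -0.5), 51: (0, -0.7), 52: (0, -0.5), 61: (0, -1),
                56: (0, 0.5), 57: (0, 0.7), 58: (0, 0.5), 64: (0, 1)}),
    # jaw drops
    26: _field({**{i: (0, 1) for i in range(5, 12)},
                **{i: (0, 1) for i in range(55, 60)},
                63: (0, 1), 64: (0, 1), 65: (0, 1)}),
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """A stimulus epoch eliciting one AU with given participation."""

    start: int
    end: int  # inclusive
    au_id: int
    participation: float = 1.0
    amp_mean: float = 10.0
    amp_sd: float = 1.0
    onset: int = 10
    offset: int = 10
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError("epoch start must be <= end")
        if not 0 <= self.participation <= 1:
            raise StructureError("participation probability must be in [0, 1]")
        if self.amp_mean < 0 or self.amp_sd < 0:
            raise StructureError("amplitudes must be >= 0")
        if self.au_id not in AU_PATTERNS:
            raise StructureError(f"no displacement pattern for AU {self.au_id}")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    def ramp(self) -> np.ndarray:
        """Trapezoidal envelope over the epoch's frames, apex value 1."""
        T = self.n_frames
        env = np.ones(T)
        up = min(self.onset, T)
        down = min(self.offset, T)
        env[:up] = np.linspace(1.0 / up, 1.0, up) if up else 1.0
        tail = np.linspace(1.0, 1.0 / down, down) if down else np.ones(0)
        env[T - down:] = np.minimum(env[T - down:], tail)
        return env

    def apex_frames(self) -> np.ndarray:
        """Absolute frame indices where the envelope equals 1."""
        return self.start + np.flatnonzero(self.ramp() >= 1.0)


@dataclass(frozen=True)
class HeadPoseNuisance:
    """Ranges of the per-frame in-plane similarity nuisance."""

    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px: float = 20.0


@dataclass
class SimulationConfig:
    n_subjects: int = 27
    n_frames: int = 500
    fps: float = 20.0
    noise_sd: float = 1.0
    shape_sd: float = 0.03        # relative per-subject affine jitter
    shape_translation_sd: float = 4.0
    head_pose: HeadPoseNuisance | None = None
    epochs: list[Epoch] = field(default_factory=list)
    noiseless_neutral: bool = False  # emit frame 0 exactly at the shape face
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise StructureError("need at least 2 subjects")
        by_au: dict[int, list[Epoch]] = {}
        for e in self.epochs:
            if not (0 <= e.start <= e.end < self.n_frames):
                raise StructureError(
                    f"epoch [{e.start}, {e.end}] outside [0, {self.n_frames})"
                )
            by_au.setdefault(e.au_id, []).append(e)
        for au, eps in by_au.items():
            eps = sorted(eps, key=lambda e: e.start)
            for a, b in zip(eps, eps[1:]):
                if b.start <= a.end:
                    raise StructureError(f"overlapping epochs for AU {au}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the generator's ground truth."""

    dataset: CohortDataset
    gt_participation: np.ndarray  # (12, T) fraction of subjects with AU present
    config: SimulationConfig

    @property
    def gt_overall(self) -> np.ndarray:
        """Ground-truth overall consistency series in percent."""
        return self.gt_participation.max(axis=0) * 100.0


def _quantize_intensity(amplitude: np.ndarray, amp_mean: float) -> np.ndarray:
    """Equal-width intensity bins over [0, 2 * amp_mean] -> codes 0-5."""
    width = 2.0 * amp_mean / 5.0 if amp_mean > 0 else 1.0
    codes = np.ceil(amplitude / width).astype(int)
    codes[amplitude <= 0] = 0
    return np.clip(codes, 0, 5)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config.seed``."""
    n, T = config.n_subjects, config.n_frames
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n)]
    au_index = {k: j for j, k in enumerate(AU_IDS)}
    recordings: list[SubjectRecording] = []
    labels: list[AULabelSequence] = []
    presence = np.zeros((n, len(AU_IDS), T), dtype=np.uint8)
    centroid = FACE_TEMPLATE.mean(axis=0)
    for i, rng in enumerate(streams):
        # per-subject shape variation
        A = np.eye(2) + rng.normal(0.0, config.shape_sd, (2, 2))
        b = rng.normal(0.0, config.shape_translation_sd, 2)
        neutral = (FACE_TEMPLATE - centroid) @ A.T + centroid + b
        disp = np.zeros((T, KPM_DIM))
        intensities = np.zeros((T, len(AU_IDS)), dtype=int)
        for epoch in config.epochs:
            participates = rng.random() < epoch.participation
            amplitude = max(0.0, rng.normal(epoch.amp_mean, epoch.amp_sd))
            if not participates:
                continue
            envelope = amplitude * epoch.ramp()
            frames = slice(epoch.start, epoch.end + 1)
            disp[frames] += envelope[:, None] * AU_PATTERNS[epoch.au_id]
            codes = _quantize_intensity(envelope, epoch.amp_mean)
            j = au_index[epoch.au_id]
            intensities[frames, j] = np.maximum(intensities[frames, j], codes)
        coords = np.repeat(neutral[None], T, axis=0)
        coords[:, :, 0] += disp[:, :N_KEYPOINTS]
        coords[:, :, 1] += disp[:, N_KEYPOINTS:]
        jitter = rng.normal(0.0, config.noise_sd, (T, N_KEYPOINTS, 2))
        if config.noiseless_neutral:
            jitter[0] = 0.0
        coords += jitter
        if config.head_pose is not None:
            coords = _apply_head_pose(coords, config.head_pose, rng)
        recordings.append(
            SubjectRecording(f"subject_{i:03d}", coords, np.arange(T),
                             fps=config.fps)
        )
        labels.append(AULabelSequence(f"subject_{i:03d}", intensities))
        presence[i] = (intensities >= 1).T
    segments = _segments_from_epochs(config.epochs, T)
    dataset = CohortDataset(recordings, labels, segments)
    gt = presence.mean(axis=0)
    return SyntheticCohort(dataset, gt, config)


def _apply_head_pose(
    coords: np.ndarray, pose: HeadPoseNuisance, rng: np.random.Generator
) -> np.ndarray:
    T = coords.shape[0]
    angles = np.deg2rad(
        rng.uniform(-pose.rotation_deg, pose.rotation_deg, T)
    )
    scales = rng.uniform(*pose.scale_range, T)
    trans = rng.uniform(-pose.translation_px, pose.translation_px, (T, 2))
    out = np.empty_like(coords)
    for t in range(T):
        c, s = np.cos(angles[t]), np.sin(angles[t])
        R = scales[t] * np.array([[c, -s], [s, c]])
        center = coords[t].mean(axis=0)
        out[t] = (coords[t] - center) @ R.T + center + trans[t]
    return out


def apply_nuisance(
    dataset: CohortDataset, pose: HeadPoseNuisance, seed: int = 0
) -> CohortDataset:
    """Apply fresh per-frame in-plane similarity nuisance to every recording."""
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(len(dataset.recordings))]
    recordings = [
        rec.with_coords(_apply_head_pose(rec.coords, pose, rng))
        for rec, rng in zip(dataset.recordings, streams)
    ]
    return CohortDataset(recordings, dataset.au_labels, dataset.segments)


def _segments_from_epochs(epochs: list[Epoch], n_frames: int) -> SegmentTable | None:
    if not epochs:
        return None
    spans = sorted(epochs, key=lambda e: e.start)
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:  # overlapping epochs across AUs: no segment table
            return None
    return SegmentTable(
        [
            Segment(e.label or f"AU{e.au_id}_{j}", e.start, e.end,
                    e.label or f"AU{e.au_id}")
            for j, e in enumerate(spans)
        ]
    )


def null_cohort(
    n: int, T: int, noise_sd: float = 1.0, seed: int = 0
) -> SyntheticCohort:
    """Pure-noise cohort (no epochs, no nuisance) for null calibration.

    Frame 0 is emitted noise-free so that, with frame 0 as the neutral
    reference, the movement vectors at every later frame are i.i.d.
    Gaussian across frames and subjects and the t / T-square null
    distributions hold exactly.
    """
    if n < 2:
        raise StructureError("need at least 2 subjects")
    return simulate_cohort(
        SimulationConfig(
            n_subjects=n, n_frames=T, noise_sd=noise_sd,
            shape_sd=0.0, shape_translation_sd=0.0,
            head_pose=None, epochs=[], noiseless_neutral=True, seed=seed,
        )
    )


def default_structured_config(
    n_subjects: int = 27,
    n_frames: int = 600,
    seed: int = 0,
    participation: float = 0.9,
    amp_mean: float = 18.0,
    noise_sd: float = 1.0,
) -> SimulationConfig:
    """Two high-participation epochs separated by null gaps.

    Used by the CLI default simulation and by end-to-end recovery checks.
    """
    q = n_frames // 12
    # AUs whose displacement fields touch many keypoints give the keypoint
    # metrics a clear signal at moderate amplitudes
    epochs = [
        Epoch(2 * q, 5 * q, au_id=26, participation=participation,
              amp_mean=amp_mean, amp_sd=amp_mean / 10.0,
              onset=max(2, q // 12), offset=max(2, q // 12), label="Happy1"),
        Epoch(7 * q, 10 * q, au_id=4, participation=participation,
              amp_mean=amp_mean, amp_sd=amp_mean / 10.0,
              onset=max(2, q // 12), offset=max(2, q // 12), label="Surprise1"),
    ]
    return SimulationConfig(
        n_subjects=n_subjects, n_frames=n_frames, noise_sd=noise_sd,
        epochs=epochs, seed=seed,
    )
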
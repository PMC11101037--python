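"""Action-unit based reference consistency metric.

The per-AU consistency at a frame is the percentage of subjects showing
that AU; the overall value is the maximum over the 12 coded AUs.  Values
therefore live on the exact grid {0, 100/n, 200/n, ..., 100}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructureError
from .io import AU_IDS, AULabelSequence


@dataclass
class AULabelMatrix:
    """Binary AU presence mu(subject, au, frame), shape (n, 12, T)."""

    mu: np.ndarray
    au_ids: tuple[int, ...] = AU_IDS
    subject_ids: tuple[str, ...] | None = None
    threshold: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.mu)
        if arr.ndim != 3 or arr.shape[1] != len(self.au_ids):
            raise StructureError(
                f"mu must be (n, {len(self.au_ids)}, T), got {arr.shape}"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise StructureError("mu entries must be binary")
        self.mu = arr.astype(np.uint8)

    @property
    def n_subjects(self) -> int:
        return self.mu.shape[0]

    @property
    def n_frames(self) -> int:
        return self.mu.shape[2]

    def au_index(self, au_id: int) -> int:
        try:
            return self.au_ids.index(au_id)
        except ValueError:
            raise StructureError(f"unknown AU id {au_id}") from None


@dataclass
class ConsistencySeries:
    """Per-frame AU consistency, overall and per AU, in percent."""

    overall: np.ndarray  # (T,)
    per_au: np.ndarray  # (12, T)
    argmax_au: np.ndarray  # (T,) AU id attaining the maximum
    n_subjects: int
    au_ids: tuple[int, ...] = AU_IDS

    def __len__(self) -> int:
        return len(self.overall)


def binarize_au(
    labels: list[AULabelSequence], threshold: int = 1
) -> AULabelMatrix:
    """Binarize intensity codes into presence: mu = 1 iff intensity >= threshold."""
    if not 1 <= threshold <= 5:
        raise StructureError("threshold must be an integer in [1, 5]")
    if not labels:
        raise StructureError("need at least one AU label sequence")
    lengths = {s.n_frames for s in labels}
    if len(lengths) != 1:
        raise StructureError(f"AU sequences have unequal lengths: {sorted(lengths)}")
    mu = np.stack([(s.intensities >= threshold).T for s in labels])
    return AULabelMatrix(
        mu,
        au_ids=labels[0].au_ids,
        subject_ids=tuple(s.subject_id for s in labels),
        threshold=threshold,
    )


def au_consistency_per_au(mu: AULabelMatrix, au_id: int, frame: int) -> float:
    """Percentage of subjects displaying ``au_id`` at ``frame``."""
    k = mu.au_index(au_id)
    if not 0 <= frame < mu.n_frames:
        raise StructureError(f"frame {frame} out of range")
    return float(mu.mu[:, k, frame].mean() * 100.0)


def au_consistency(mu: AULabelMatrix, frame: int) -> float:
    """Overall consistency at ``frame``: max over AUs of the per-AU value."""
    if not 0 <= frame < mu.n_frames:
        raise StructureError(f"frame {frame} out of range")
    return float(mu.mu[:, :, frame].mean(axis=0).max() * 100.0)


def au_consistency_series(mu: AULabelMatrix) -> ConsistencySeries:
    """Overall and per-AU consistency for every frame."""
    per_au = mu.mu.mean(axis=0) * 100.0  # (12, T)
    overall = per_au.max(axis=0)
    argmax = np.asarray(mu.au_ids)[per_au.argmax(axis=0)]
    return ConsistencySeries(overall, per_au, argmax, mu.n_subjects, mu.au_ids)
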
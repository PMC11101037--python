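"""Reading and writing cohort data in plain-text formats.

Canonical on-disk layout of a cohort directory::

    cohort/
        landmarks/<subject_id>.csv   frame,x_0,...,x_65,y_0,...,y_65
        au_labels/<subject_id>.csv   frame,AU1,AU2,AU4,...,AU26  (intensity 0-5)
        segments.csv                 name,start_frame,end_frame,emotion

All files are comma- or tab-separated with a header row.  Frames are
0-based and must be contiguous; segment (start, end) bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, StructureError

#: Number of tracked facial keypoints per frame.
N_KEYPOINTS = 66
#: Length of a packed movement vector (x block then y block).
KPM_DIM = 2 * N_KEYPOINTS
#: The 12 coded action units, in canonical column order.
AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 9, 12, 15, 17, 20, 25, 26)

LANDMARK_COLUMNS = (
    ["frame"]
    + [f"x_{i}" for i in range(N_KEYPOINTS)]
    + [f"y_{i}" for i in range(N_KEYPOINTS)]
)
AU_COLUMNS = ["frame"] + [f"AU{k}" for k in AU_IDS]
SEGMENT_COLUMNS = ["name", "start_frame", "end_frame", "emotion"]


@dataclass(frozen=True)
class KeypointFrame:
    """A single frame of 66 (x, y) keypoints in image (y-down) pixel units."""

    frame_index: int
    points: np.ndarray  # (66, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_KEYPOINTS, 2):
            raise StructureError(
                f"expected {N_KEYPOINTS} (x, y) points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise StructureError("keypoint coordinates must be finite")
        if self.frame_index < 0:
            raise StructureError("frame_index must be >= 0")
        object.__setattr__(self, "points", pts)


@dataclass
class SubjectRecording:
    """Dense landmark trajectory of one subject.

    ``coords`` has shape (T, 66, 2); ``frame_index`` is strictly increasing
    by 1 (dense capture — missing frames are an error, not interpolated).
    """

    subject_id: str
    coords: np.ndarray
    frame_index: np.ndarray
    fps: float = 20.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise StructureError(
                f"coords must have shape (T, {N_KEYPOINTS}, 2), "
                f"got {self.coords.shape}"
            )
        if self.frame_index.shape != (self.coords.shape[0],):
            raise StructureError("frame_index length must match coords")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"subject {self.subject_id!r}: non-finite coordinates"
            )
        if len(self.frame_index) and np.any(np.diff(self.frame_index) != 1):
            raise StructureError(
                f"subject {self.subject_id!r}: frame indices must be "
                "contiguous and strictly increasing by 1"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> KeypointFrame:
        return KeypointFrame(int(self.frame_index[i]), self.coords[i])

    def with_coords(self, coords: np.ndarray) -> "SubjectRecording":
        """Copy of this recording with replaced coordinates."""
        return SubjectRecording(
            self.subject_id, coords, self.frame_index.copy(), self.fps
        )


@dataclass
class AULabelSequence:
    """Per-frame intensity codes (0-5) for the 12 coded action units."""

    subject_id: str
    intensities: np.ndarray  # (T, 12) int
    au_ids: tuple[int, ...] = AU_IDS

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.shape[1] != len(self.au_ids):
            raise StructureError(
                f"intensities must have shape (T, {len(self.au_ids)}), "
                f"got {arr.shape}"
            )
        if arr.size and (arr.min() < 0 or arr.max() > 5):
            bad = arr[(arr < 0) | (arr > 5)][0]
            raise ParseError(
                f"subject {self.subject_id!r}: AU intensity {bad} outside [0, 5]"
            )
        self.intensities = arr.astype(int)

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class Segment:
    name: str
    start_frame: int
    end_frame: int
    emotion: str

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise StructureError(
                f"segment {self.name!r}: start {self.start_frame} > "
                f"end {self.end_frame}"
            )


@dataclass
class SegmentTable:
    """Ordered, non-overlapping emotion segments with inclusive frame bounds."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_frame)
        for a, b in zip(segs, segs[1:]):
            if b.start_frame <= a.end_frame:
                raise StructureError(
                    f"segments {a.name!r} and {b.name!r} overlap"
                )
        self.segments = segs

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, i: int) -> Segment:
        return self.segments[i]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]


@dataclass
class CohortDataset:
    """Aligned multi-subject recordings plus optional AU labels and segments."""

    recordings: list[SubjectRecording]
    au_labels: list[AULabelSequence] | None = None
    segments: SegmentTable | None = None

    def __post_init__(self) -> None:
        if len(self.recordings) < 2:
            raise StructureError("a cohort needs at least 2 subjects")
        lengths = {r.n_frames for r in self.recordings}
        if len(lengths) != 1:
            raise StructureError(
                f"recordings have unequal frame counts: {sorted(lengths)}"
            )
        if self.au_labels is not None:
            if len(self.au_labels) != len(self.recordings):
                raise StructureError(
                    "au_labels count does not match number of recordings"
                )
            for rec, au in zip(self.recordings, self.au_labels):
                if au.n_frames != rec.n_frames:
                    raise StructureError(
                        f"subject {rec.subject_id!r}: AU label frame count "
                        f"{au.n_frames} != landmark frame count {rec.n_frames}"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    @property
    def n_frames(self) -> int:
        return self.recordings[0].n_frames

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]


@dataclass
class MetricSeries:
    """One consistency value per frame for a named metric."""

    name: str
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise StructureError("metric series must be 1-D")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, expected_columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != list(expected_columns):
        raise ParseError(
            f"{path}: expected columns {list(expected_columns)[:4]}... "
            f"({len(expected_columns)} total), got {list(df.columns)[:4]}... "
            f"({len(df.columns)} total)"
        )
    for col in expected_columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if col != "name" and col != "emotion" and len(bad):
            raise ParseError(f"{path}: malformed value in row {bad[0]}, column {col!r}")
    return df


def read_landmarks(
    path: str | Path, schema: str = "flat", fps: float = 20.0
) -> SubjectRecording:
    """Read a landmark trajectory file into a :class:`SubjectRecording`.

    ``schema='flat'`` is the canonical dialect: one row per frame with a
    header ``frame,x_0,...,x_65,y_0,...,y_65``.
    """
    if schema != "flat":
        raise ParseError(f"unknown landmark schema {schema!r}")
    path = Path(path)
    df = _read_table(path, LANDMARK_COLUMNS)
    frames = df["frame"].to_numpy(dtype=int)
    xs = df[[f"x_{i}" for i in range(N_KEYPOINTS)]].to_numpy(dtype=float)
    ys = df[[f"y_{i}" for i in range(N_KEYPOINTS)]].to_numpy(dtype=float)
    coords = np.stack([xs, ys], axis=-1)
    return SubjectRecording(path.stem, coords, frames, fps=fps)


def write_landmarks(recording: SubjectRecording, path: str | Path) -> None:
    data = {"frame": recording.frame_index}
    for i in range(N_KEYPOINTS):
        data[f"x_{i}"] = recording.coords[:, i, 0]
    for i in range(N_KEYPOINTS):
        data[f"y_{i}"] = recording.coords[:, i, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_au_labels(path: str | Path) -> AULabelSequence:
    """Read per-frame AU intensity codes (header ``frame,AU1,...,AU26``)."""
    path = Path(path)
    df = _read_table(path, AU_COLUMNS)
    intensities = df[[f"AU{k}" for k in AU_IDS]].to_numpy()
    if not np.issubdtype(intensities.dtype, np.integer):
        if not np.allclose(intensities, np.round(intensities)):
            raise ParseError(f"{path}: AU intensities must be integer codes")
        intensities = np.round(intensities).astype(int)
    return AULabelSequence(path.stem, intensities)


def write_au_labels(labels: AULabelSequence, path: str | Path) -> None:
    data = {"frame": np.arange(labels.n_frames)}
    for j, k in enumerate(labels.au_ids):
        data[f"AU{k}"] = labels.intensities[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_segments(path: str | Path) -> SegmentTable:
    """Read a ``name,start_frame,end_frame,emotion`` segment file."""
    df = _read_table(Path(path), SEGMENT_COLUMNS)
    segments = [
        Segment(str(r["name"]), int(r["start_frame"]), int(r["end_frame"]),
                str(r["emotion"]))
        for _, r in df.iterrows()
    ]
    return SegmentTable(segments)


def write_segments(table: SegmentTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": s.name, "start_frame": s.start_frame,
             "end_frame": s.end_frame, "emotion": s.emotion}
            for s in table
        ],
        columns=SEGMENT_COLUMNS,
    ).to_csv(path, index=False)


def write_metric_series(series: MetricSeries, path: str | Path) -> None:
    """Write a metric series as a two-column TSV (frame, value)."""
    if not np.all(np.isfinite(series.values)):
        raise StructureError(f"metric {series.name!r}: non-finite values")
    df = pd.DataFrame(
        {"frame": np.arange(len(series)), "value": series.values}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metric_series(path: str | Path, name: str | None = None) -> MetricSeries:
    path = Path(path)
    df = _read_table(path, ["frame", "value"])
    return MetricSeries(name or path.stem, df["value"].to_numpy(dtype=float))


def write_kpm(subject_id: str, values: np.ndarray, path: str | Path) -> None:
    """Write a (T, 132) movement matrix as TSV with dx_*/dy_* columns."""
    values = np.asarray(values, dtype=float)
    data = {"frame": np.arange(values.shape[0])}
    for i in range(N_KEYPOINTS):
        data[f"dx_{i}"] = values[:, i]
    for i in range(N_KEYPOINTS):
        data[f"dy_{i}"] = values[:, N_KEYPOINTS + i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_kpm(path: str | Path) -> np.ndarray:
    cols = (
        ["frame"]
        + [f"dx_{i}" for i in range(N_KEYPOINTS)]
        + [f"dy_{i}" for i in range(N_KEYPOINTS)]
    )
    df = _read_table(Path(path), cols)
    return df[cols[1:]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# cohort directory layout
# ---------------------------------------------------------------------------


def load_cohort(directory: str | Path, fps: float = 20.0) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from a cohort directory."""
    directory = Path(directory)
    lm_dir = directory / "landmarks"
    if not lm_dir.is_dir():
        raise ParseError(f"no landmarks/ directory under {directory}")
    recordings = [
        read_landmarks(p, fps=fps) for p in sorted(lm_dir.glob("*.csv"))
    ]
    au_dir = directory / "au_labels"
    au_labels = None
    if au_dir.is_dir():
        by_id = {p.stem: p for p in au_dir.glob("*.csv")}
        missing = [r.subject_id for r in recordings if r.subject_id not in by_id]
        if missing:
            raise StructureError(f"AU label files missing for subjects {missing}")
        au_labels = [read_au_labels(by_id[r.subject_id]) for r in recordings]
    seg_path = directory / "segments.csv"
    segments = read_segments(seg_path) if seg_path.exists() else None
    return CohortDataset(recordings, au_labels, segments)


def write_cohort(cohort: CohortDataset, directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "landmarks").mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_landmarks(rec, directory / "landmarks" / f"{rec.subject_id}.csv")
    if cohort.au_labels is not None:
        (directory / "au_labels").mkdir(exist_ok=True)
        for au in cohort.au_labels:
            write_au_labels(au, directory / "au_labels" / f"{au.subject_id}.csv")
    if cohort.segments is not None:
        write_segments(cohort.segments, directory / "segments.csv")
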
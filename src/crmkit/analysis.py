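"""Cohort-level analysis: consistency classes, per-segment distribution
tables, KL-divergence between class distributions, and regression agreement.

Classes are derived from the empirical CDF of a series: nearest-rank
percentiles at (30, 60, 90) split the frames into Inconsistent, Low, Mild
and High Consistent, with half-open intervals and the top interval closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, StructureError
from .io import SegmentTable

CLASS_NAMES = ("Inconsistent", "Low Consistent", "Mild Consistent",
               "High Consistent")

#: Zero-cell smoothing and direction convention that reproduce the published
#: divergence benchmarks; both are exposed as knobs.
DEFAULT_KL_EPSILON = 1e-10
DEFAULT_KL_DIRECTION = "au_to_metric"  # or "metric_to_au"


@dataclass
class ClassBoundaries:
    """Three percentile boundaries splitting a series into four classes."""

    metric_name: str
    boundaries: np.ndarray  # (3,)
    percentiles: tuple[float, float, float] = (30.0, 60.0, 90.0)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (3,):
            raise StructureError("need exactly 3 boundaries")
        if np.any(np.diff(self.boundaries) < 0):
            raise StructureError("boundaries must be non-decreasing")


@dataclass
class ClassDistributionTable:
    """Per-segment percentage of frames in each consistency class."""

    row_names: list[str]
    values: np.ndarray  # (n_rows, 4) percentages
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.row_names), len(self.class_names)
        ):
            raise StructureError("table shape does not match row/class names")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_names, columns=list(self.class_names)
        )

    def rounded(self) -> pd.DataFrame:
        """Display rounding: half-up to integers (rows may sum to 99-101)."""
        rounded = np.floor(self.values + 0.5).astype(int)
        return pd.DataFrame(
            rounded, index=self.row_names, columns=list(self.class_names)
        )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise StructureError(f"R^2 out of [0, 1]: {self.r2}")
        self.r2 = float(min(max(self.r2, 0.0), 1.0))


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Type-1 (nearest-rank) empirical percentile."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise StructureError("empty series")
    if p <= 0:
        return float(v[0])
    rank = math.ceil(p / 100.0 * len(v))
    return float(v[min(rank, len(v)) - 1])


def class_boundaries(
    values: np.ndarray,
    percentiles: Sequence[float] = (30.0, 60.0, 90.0),
    metric_name: str = "",
) -> ClassBoundaries:
    """Empirical nearest-rank percentile boundaries for the four classes."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise StructureError("series must be 1-D with at least 4 values")
    if len(percentiles) != 3:
        raise StructureError("need exactly 3 percentiles")
    bounds = np.array([nearest_rank_percentile(v, p) for p in percentiles])
    return ClassBoundaries(metric_name, bounds, tuple(percentiles))


def classify(values: np.ndarray, boundaries: ClassBoundaries) -> np.ndarray:
    """Assign each value a class label 0..3.

    Intervals are half-open ([b0, b1) etc.) with the top interval closed;
    a value equal to a boundary goes to the upper class, so degenerate
    (equal) boundaries push everything into the top class containing it.
    """
    v = np.asarray(values, dtype=float)
    labels = np.zeros(len(v), dtype=int)
    for b in boundaries.boundaries:
        labels += (v >= b).astype(int)
    return labels


def segment_distribution(
    labels: np.ndarray,
    segments: SegmentTable,
    extend_to_isg: bool = True,
) -> ClassDistributionTable:
    """Percentage of each segment's frames falling in each class.

    With ``extend_to_isg`` every segment is stretched to the frame before
    the next segment's start (the last one to the end of the recording),
    absorbing the inter-segment gap.
    """
    labels = np.asarray(labels, dtype=int)
    n_frames = len(labels)
    segs = list(segments)
    rows = []
    values = np.zeros((len(segs), len(CLASS_NAMES)))
    for i, seg in enumerate(segs):
        if seg.start_frame >= n_frames or seg.end_frame >= n_frames:
            raise StructureError(
                f"segment {seg.name!r} [{seg.start_frame}, {seg.end_frame}] "
                f"exceeds series length {n_frames}"
            )
        start = seg.start_frame
        if extend_to_isg:
            end = segs[i + 1].start_frame - 1 if i + 1 < len(segs) else n_frames - 1
        else:
            end = seg.end_frame
        window = labels[start:end + 1]
        counts = np.bincount(window, minlength=len(CLASS_NAMES))
        values[i] = counts / len(window) * 100.0
        rows.append(seg.name)
    return ClassDistributionTable(rows, values)


def kl_divergence(
    p: np.ndarray, q: np.ndarray, epsilon: float = DEFAULT_KL_EPSILON
) -> float:
    """KL divergence (nats) between two non-negative rows.

    Rows are normalized to probabilities; zero cells in both rows are
    replaced by ``epsilon`` and the rows renormalized, keeping the
    divergence finite in the presence of empty classes.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise StructureError("p and q must be matching 1-D rows")
    if np.any(p < 0) or np.any(q < 0):
        raise StructureError("distribution rows must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise StructureError("distribution rows must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    p = np.where(p == 0, epsilon, p)
    q = np.where(q == 0, epsilon, q)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def avg_rowwise_kl(
    table_metric: ClassDistributionTable,
    table_au: ClassDistributionTable,
    direction: str = DEFAULT_KL_DIRECTION,
    epsilon: float = DEFAULT_KL_EPSILON,
) -> float:
    """Row-wise KL divergence between two class tables, averaged over rows.

    Rows are paired by name.  ``direction`` selects the operand order:
    ``"au_to_metric"`` computes KL(au_row || metric_row) per row (the
    default), ``"metric_to_au"`` the reverse.
    """
    if table_metric.row_names != table_au.row_names:
        raise StructureError(
            "tables have different rows: "
            f"{table_metric.row_names} vs {table_au.row_names}"
        )
    if direction not in ("au_to_metric", "metric_to_au"):
        raise StructureError(f"unknown direction {direction!r}")
    divs = []
    for m_row, a_row in zip(table_metric.values, table_au.values):
        if direction == "au_to_metric":
            divs.append(kl_divergence(a_row, m_row, epsilon))
        else:
            divs.append(kl_divergence(m_row, a_row, epsilon))
    return float(np.mean(divs))


def fit_r2(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Simple OLS of y on x; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StructureError("x and y must be matching 1-D series, length >= 3")
    if np.ptp(x) == 0:
        raise FitError("constant x: regression is degenerate")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y.mean()), 0.0)
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue**2))


@dataclass
class MetricComparison:
    name: str
    r2: float
    slope: float
    intercept: float
    avg_kl: float


def compare_metrics(
    au_values: np.ndarray,
    metric_values: dict[str, np.ndarray],
    segments: SegmentTable,
    percentiles: Sequence[float] = (30.0, 60.0, 90.0),
    direction: str = DEFAULT_KL_DIRECTION,
    epsilon: float = DEFAULT_KL_EPSILON,
    extend_to_isg: bool = True,
) -> dict:
    """Compare keypoint metrics against the AU reference series.

    For every metric: OLS agreement (R^2, slope, intercept) with the AU
    series and the row-wise averaged KL divergence between the two
    class-distribution tables.  Returns a JSON-serializable report with
    rankings by R^2 (descending) and by KL (ascending).
    """
    au_values = np.asarray(au_values, dtype=float)
    au_bounds = class_boundaries(au_values, percentiles, "au_consistency")
    au_table = segment_distribution(
        classify(au_values, au_bounds), segments, extend_to_isg
    )
    comparisons: list[MetricComparison] = []
    tables: dict[str, ClassDistributionTable] = {}
    for name, values in metric_values.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(au_values):
            raise StructureError(
                f"metric {name!r} length {len(values)} != AU series "
                f"length {len(au_values)}"
            )
        fit = fit_r2(values, au_values)
        bounds = class_boundaries(values, percentiles, name)
        table = segment_distribution(
            classify(values, bounds), segments, extend_to_isg
        )
        tables[name] = table
        comparisons.append(
            MetricComparison(
                name, fit.r2, fit.slope, fit.intercept,
                avg_rowwise_kl(table, au_table, direction, epsilon),
            )
        )
    by_r2 = sorted(comparisons, key=lambda c: -c.r2)
    by_kl = sorted(comparisons, key=lambda c: c.avg_kl)
    return {
        "metrics": {
            c.name: {
                "r2": c.r2, "slope": c.slope,
                "intercept": c.intercept, "avg_kl": c.avg_kl,
            }
            for c in comparisons
        },
        "ranking_by_r2": [c.name for c in by_r2],
        "ranking_by_kl": [c.name for c in by_kl],
        "options": {
            "percentiles": list(percentiles),
            "kl_direction": direction,
            "kl_epsilon": epsilon,
            "extend_to_isg": extend_to_isg,
        },
        "au_table": au_table.to_dataframe().to_dict(orient="index"),
        "metric_tables": {
            name: t.to_dataframe().to_dict(orient="index")
            for name, t in tables.items()
        },
    }
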
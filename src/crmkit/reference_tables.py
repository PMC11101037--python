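"""Published benchmark class-distribution tables.

Per-emotion-segment percentages of frames in the four consistency classes
(Inconsistent, Low, Mild, High Consistent) reported for a 27-subject,
4845-frame cohort: one table for the AU-based reference metric and one for
each of the five keypoint-based metrics.  These rows serve as fixed inputs
for reproducing the published cross-metric divergence benchmark.
"""

from __future__ import annotations

from .analysis import ClassDistributionTable

SEGMENT_ORDER = [
    "Happy1", "Happy2", "Surprise1", "Fear", "Disgust1", "Disgust2",
    "Sadness1", "Sadness2", "Surprise2",
]

_ROWS: dict[str, dict[str, list[float]]] = {
    "au_consistency": {
        "Happy1": [6, 14, 6, 74],
        "Happy2": [0, 14, 60, 27],
        "Surprise1": [0, 17, 77, 6],
        "Fear": [0, 20, 69, 11],
        "Disgust1": [1, 45, 49, 5],
        "Disgust2": [1, 22, 77, 0],
        "Sadness1": [89, 11, 0, 0],
        "Sadness2": [100, 0, 0, 0],
        "Surprise2": [33, 31, 19, 16],
    },
    "avg_t": {
        "Happy1": [0, 17, 13, 70],
        "Happy2": [0, 13, 56, 30],
        "Surprise1": [0, 21, 75, 4],
        "Fear": [0, 47, 53, 0],
        "Disgust1": [0, 20, 55, 25],
        "Disgust2": [0, 67, 33, 0],
        "Sadness1": [67, 33, 0, 0],
        "Sadness2": [74, 26, 0, 0],
        "Surprise2": [49, 19, 32, 0],
    },
    "max_t": {
        "Happy1": [0, 10, 44, 45],
        "Happy2": [0, 11, 70, 19],
        "Surprise1": [0, 50, 45, 5],
        "Fear": [1, 68, 31, 0],
        "Disgust1": [0, 24, 36, 40],
        "Disgust2": [0, 36, 58, 6],
        "Sadness1": [68, 29, 3, 0],
        "Sadness2": [79, 21, 0, 0],
        "Surprise2": [44, 33, 22, 0],
    },
    "avg_t2": {
        "Happy1": [0, 18, 18, 64],
        "Happy2": [0, 11, 59, 31],
        "Surprise1": [0, 26, 69, 5],
        "Fear": [0, 52, 48, 0],
        "Disgust1": [0, 21, 51, 28],
        "Disgust2": [0, 64, 36, 0],
        "Sadness1": [68, 32, 0, 0],
        "Sadness2": [74, 26, 0, 0],
        "Surprise2": [48, 19, 32, 0],
    },
    "max_t2": {
        "Happy1": [0, 14, 44, 42],
        "Happy2": [0, 13, 63, 24],
        "Surprise1": [0, 46, 50, 4],
        "Fear": [0, 62, 38, 0],
        "Disgust1": [0, 22, 39, 39],
        "Disgust2": [0, 42, 52, 6],
        "Sadness1": [66, 32, 2, 0],
        "Sadness2": [75, 25, 0, 0],
        "Surprise2": [49, 25, 26, 0],
    },
    "pca_t2": {
        "Happy1": [0, 8, 43, 49],
        "Happy2": [0, 4, 74, 22],
        "Surprise1": [0, 46, 48, 6],
        "Fear": [0, 61, 39, 0],
        "Disgust1": [0, 25, 44, 31],
        "Disgust2": [0, 36, 54, 10],
        "Sadness1": [68, 32, 0, 0],
        "Sadness2": [78, 22, 0, 0],
        "Surprise2": [44, 38, 18, 0],
    },
}

#: Published row-wise averaged KL divergences (nats) of each keypoint metric's
#: table against the AU table, for reference in benchmark comparisons.
PUBLISHED_AVG_KL = {
    "avg_t": 0.92,
    "max_t": 0.98,
    "avg_t2": 0.93,
    "max_t2": 0.98,
    "pca_t2": 0.96,
}


def published_table(metric: str) -> ClassDistributionTable:
    """The published class-distribution table for ``metric``.

    ``metric`` is one of ``au_consistency``, ``avg_t``, ``max_t``,
    ``avg_t2``, ``max_t2``, ``pca_t2``.
    """
    try:
        rows = _ROWS[metric]
    except KeyError:
        raise KeyError(
            f"no published table for {metric!r}; available: {sorted(_ROWS)}"
        ) from None
    return ClassDistributionTable(
        SEGMENT_ORDER, [rows[name] for name in SEGMENT_ORDER]
    )
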
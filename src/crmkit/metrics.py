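"""Per-frame consistency metrics built from cohort movement vectors.

Three statistical models turn an (n_subjects x 132) slice of movement
vectors at one frame into a scalar:

* independent univariate Gaussian per coordinate -> one-sample t-scores,
  summarized by their mean magnitude (``avg_t``) or maximum (``max_t``);
* independent bivariate Gaussian per keypoint -> one-sample Hotelling
  T-square scores, summarized likewise (``avg_t2`` / ``max_t2``);
* multivariate Gaussian after PCA dimensionality reduction -> a single
  Hotelling T-square on the k-dim score vectors (``pca_t2``).

All tests are against the null of zero mean movement (neutral face).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSamplesError, StructureError
from .geometry import KPMSeries
from .io import KPM_DIM, N_KEYPOINTS, MetricSeries

METRIC_NAMES = ("avg_t", "max_t", "avg_t2", "max_t2", "pca_t2")

#: Signed cap applied to t-scores of zero-variance, nonzero-mean coordinates.
DEFAULT_T_CAP = 1e6
#: Relative ridge added to singular per-keypoint covariance matrices.
DEFAULT_RIDGE = 1e-8
#: Absolute tolerance below which a coordinate counts as zero-variance.
#: Registration can pin coordinates exactly to the reference; their float
#: residuals (~1e-11 px) would otherwise produce arbitrary t-scores.
DEFAULT_ZERO_TOL = 1e-8


def t_scores(
    slice_: np.ndarray,
    cap: float = DEFAULT_T_CAP,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> np.ndarray:
    """One-sample t-scores per coordinate for an (n, 132) cohort slice.

    t_i = mean_i / (sd_i / sqrt(n)) with ddof=1.  Zero-variance convention
    (sd below ``zero_tol``): t = 0 when the mean is also (numerically)
    zero, otherwise a signed cap.
    """
    X = np.asarray(slice_, dtype=float)
    if X.ndim != 2:
        raise StructureError("cohort slice must be 2-D (subjects x dims)")
    n = X.shape[0]
    if n < 2:
        raise InsufficientSamplesError("t-scores need at least 2 subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd <= zero_tol
    t[zero_sd & (np.abs(mean) <= zero_tol)] = 0.0
    big = zero_sd & (np.abs(mean) > zero_tol)
    t[big] = np.sign(mean[big]) * cap
    return t


def avg_t(t: np.ndarray) -> float:
    """Mean magnitude of the per-coordinate t-scores."""
    return float(np.mean(np.abs(t)))


def max_t(t: np.ndarray, literal_scaling: bool = False) -> float:
    """Maximum t-score magnitude; ``literal_scaling`` divides by the
    number of coordinates (kept as an option, off by default)."""
    m = float(np.max(np.abs(t)))
    return m / len(t) if literal_scaling else m


def hotelling_t2(samples: np.ndarray, ridge: float = DEFAULT_RIDGE) -> float:
    """One-sample Hotelling T-square of (n, p) samples against a zero mean.

    t2 = n * xbar' S^-1 xbar with the ddof=1 sample covariance S.  Singular
    covariances get a relative ridge (lambda * mean(diag) * I) and a warning;
    an all-zero covariance with zero mean returns 0.
    """
    X = np.asarray(samples, dtype=float)
    n, p = X.shape
    if n < 2:
        raise InsufficientSamplesError("Hotelling T-square needs n >= 2")
    if n <= p:
        raise InsufficientSamplesError(
            f"Hotelling T-square needs more samples (n={n}) than "
            f"dimensions (p={p}); reduce the dimensionality"
        )
    xbar = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    diag_mean = float(np.mean(np.diag(S)))
    if diag_mean <= DEFAULT_ZERO_TOL**2:
        if np.all(np.abs(xbar) <= DEFAULT_ZERO_TOL):
            return 0.0
        warnings.warn("zero covariance with nonzero mean; ridge applied",
                      RuntimeWarning, stacklevel=2)
        return float(n * xbar @ xbar / ridge)
    sv = np.linalg.svd(S, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-12:
        # numerically singular (e.g. a coordinate pinned by registration)
        warnings.warn("singular covariance; ridge applied",
                      RuntimeWarning, stacklevel=2)
        S = S + ridge * diag_mean * np.eye(p)
    sol = np.linalg.solve(S, xbar)
    return float(n * xbar @ sol)


def hotelling_t2_per_keypoint(
    slice_: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Hotelling T-square per keypoint for an (n, 132) cohort slice.

    Keypoint i uses columns (i, 66+i) of the packed movement vector.
    Returns 66 non-negative scores.
    """
    X = np.asarray(slice_, dtype=float)
    if X.ndim != 2 or X.shape[1] != KPM_DIM:
        raise StructureError(f"cohort slice must be (n, {KPM_DIM})")
    n = X.shape[0]
    if n < 3:
        raise InsufficientSamplesError(
            "per-keypoint Hotelling T-square needs at least 3 subjects"
        )
    out = np.empty(N_KEYPOINTS)
    for i in range(N_KEYPOINTS):
        out[i] = hotelling_t2(X[:, [i, N_KEYPOINTS + i]], ridge=ridge)
    return out


def avg_t2(t2: np.ndarray) -> float:
    """Mean of the per-keypoint Hotelling scores."""
    return float(np.mean(t2))


def max_t2(t2: np.ndarray, literal_scaling: bool = False) -> float:
    m = float(np.max(t2))
    return m / len(t2) if literal_scaling else m


# ---------------------------------------------------------------------------
# PCA model
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Truncated (by default uncentered) SVD factorization Y ~ P @ Q.

    ``P`` is (132, k) with orthonormal columns, ``Q`` is (k, m).  Uncentered
    decomposition keeps the origin (neutral face) fixed so that the zero-mean
    null hypothesis transfers to score space; a centered variant stores the
    removed mean.
    """

    P: np.ndarray
    Q: np.ndarray
    k: int
    explained_variance_ratio: np.ndarray
    mean: np.ndarray | None = None  # set only for centered models

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Project (..., 132) vectors onto the k component scores."""
        V = np.asarray(vectors, dtype=float)
        if self.mean is not None:
            V = V - self.mean
        return V @ self.P


def pca_reduce(
    pooled: np.ndarray,
    k: int | None = None,
    variance_target: float | None = None,
    center: bool = False,
) -> PCAModel:
    """Fit a rank-k SVD model to the pooled (132, m) data matrix.

    Exactly one of ``k`` / ``variance_target`` selects the rank; with a
    variance target, k is the smallest rank whose cumulative explained
    variance reaches the target.
    """
    Y = np.asarray(pooled, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != KPM_DIM:
        raise StructureError(f"pooled matrix must be ({KPM_DIM}, m)")
    m = Y.shape[1]
    mean = None
    if center:
        mean = Y.mean(axis=1)
        Y = Y - mean[:, None]
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    total = float(np.sum(s**2))
    evr_full = s**2 / total if total > 0 else np.zeros_like(s)
    if variance_target is not None:
        if not 0 < variance_target <= 1:
            raise StructureError("variance_target must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(evr_full), variance_target) + 1)
        k = min(k, len(s))
    if k is None:
        raise StructureError("specify k or variance_target")
    if not 1 <= k < min(KPM_DIM, m):
        raise StructureError(
            f"k={k} must satisfy 1 <= k < min({KPM_DIM}, m={m})"
        )
    P = U[:, :k]
    Q = (s[:k, None] * Vt[:k])
    return PCAModel(P, Q, k, evr_full[:k], mean=mean)


def pca_t2(scores: np.ndarray, ridge: float = DEFAULT_RIDGE) -> float:
    """Hotelling T-square of (n, k) component scores against a zero mean."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise StructureError("scores must be 2-D (subjects x components)")
    return hotelling_t2(X, ridge=ridge)


# ---------------------------------------------------------------------------
# time series driver
# ---------------------------------------------------------------------------


def _stack_cohort(kpm_list: list[KPMSeries]) -> np.ndarray:
    if len(kpm_list) < 2:
        raise InsufficientSamplesError("need at least 2 subjects")
    lengths = {s.n_frames for s in kpm_list}
    if len(lengths) != 1:
        raise StructureError(f"KPM series lengths differ: {sorted(lengths)}")
    return np.stack([s.values for s in kpm_list])  # (n, T, 132)


def metric_timeseries(
    kpm_list: list[KPMSeries],
    metric: str,
    *,
    k: int = 5,
    variance_target: float | None = None,
    literal_scaling: bool = False,
    cap: float = DEFAULT_T_CAP,
    ridge: float = DEFAULT_RIDGE,
    center_pca: bool = False,
) -> MetricSeries:
    """Apply a named metric frame-by-frame over a cohort of KPM series."""
    if metric not in METRIC_NAMES:
        raise StructureError(
            f"unknown metric {metric!r}; choose from {METRIC_NAMES}"
        )
    X = _stack_cohort(kpm_list)  # (n, T, 132)
    n, T, _ = X.shape
    values = np.empty(T)
    meta: dict = {"n": n, "literal_scaling": literal_scaling}
    if metric in ("avg_t", "max_t"):
        for t in range(T):
            ts = t_scores(X[:, t, :], cap=cap)
            values[t] = avg_t(ts) if metric == "avg_t" else max_t(
                ts, literal_scaling
            )
    elif metric in ("avg_t2", "max_t2"):
        for t in range(T):
            t2 = hotelling_t2_per_keypoint(X[:, t, :], ridge=ridge)
            values[t] = avg_t2(t2) if metric == "avg_t2" else max_t2(
                t2, literal_scaling
            )
    else:  # pca_t2
        pooled = X.reshape(n * T, KPM_DIM).T  # (132, n*T)
        model = pca_reduce(
            pooled, k=None if variance_target else k,
            variance_target=variance_target, center=center_pca,
        )
        meta["k"] = model.k
        scores = model.transform(X)  # (n, T, k)
        for t in range(T):
            values[t] = pca_t2(scores[:, t, :], ridge=ridge)
    return MetricSeries(metric, values, meta)
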
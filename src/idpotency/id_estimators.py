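"""Intrinsic-dimension estimators for point clouds.

Two families are provided:

* **TWO-NN** (geometric): for each point the ratio mu = r2/r1 of the
  distances to its second and first nearest neighbors follows, on a locally
  uniform d-dimensional manifold, the Pareto law F(mu) = 1 - mu^(-d).
  The dimension is recovered either by maximum likelihood,
  d = n / sum(ln mu_i), or by an origin-constrained least-squares fit of
  -ln(1 - F) against ln mu on the empirical CDF, optionally discarding the
  largest-mu tail where the local-uniformity assumption is weakest.

* **PCA** (projective): the eigenvalue spectrum of the data covariance
  matrix yields either the number of components needed to reach a variance
  threshold, or the continuous participation ratio (sum(l))^2 / sum(l^2).

TWO-NN uses only local neighbor statistics, which makes it robust to
manifold curvature and to small outlier sub-populations; PCA variants see
only global linear structure. Exact (non-approximate) neighbor search is
used throughout, with ties broken by point index, and exact coordinate
duplicates collapsed to a single representative (r1 = 0 would make mu
undefined; low-depth cells can collide after normalization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateCloudError, EstimatorError
from .io_formats import ExpressionMatrix

__all__ = [
    "PointCloud",
    "MuSample",
    "IDEstimate",
    "twonn_mu",
    "twonn_mle",
    "twonn_cdf_fit",
    "pca_id",
    "pca_participation_ratio",
    "estimate_id",
    "ESTIMATOR_METHODS",
]


@dataclass
class PointCloud:
    """An n x m set of real coordinates with optional point identifiers."""

    coords: np.ndarray
    point_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise DegenerateCloudError("coordinates must be a 2-d array")
        if not np.isfinite(self.coords).all():
            raise DegenerateCloudError("coordinates contain non-finite values")
        if self.point_ids is not None:
            self.point_ids = np.asarray(self.point_ids, dtype=object)
            if len(self.point_ids) != self.coords.shape[0]:
                raise DegenerateCloudError("one id per point required")

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix) -> "PointCloud":
        return cls(expr.values, expr.cell_ids)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class MuSample:
    """Per-point second/first neighbor distance ratios mu_i >= 1."""

    mu: np.ndarray
    n_used: int
    n_dropped_duplicates: int = 0
    r1: np.ndarray | None = None
    r2: np.ndarray | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(self.mu < 1.0 - 1e-12):
            raise EstimatorError("mu ratios below 1: r2 < r1 is impossible")
        self.mu = np.maximum(self.mu, 1.0)


@dataclass
class IDEstimate:
    """A single intrinsic-dimension value with method tag and diagnostics."""

    value: float
    method: str
    n_points: int
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        diag = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.diagnostics.items()
        }
        return {
            "method": self.method,
            "value": float(self.value),
            "n_points": int(self.n_points),
            "diagnostics": diag,
        }


def _collapse_duplicates(coords: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the first occurrence of each exact duplicate coordinate row."""
    _, first = np.unique(coords, axis=0, return_index=True)
    keep = np.sort(first)
    return coords[keep], coords.shape[0] - keep.size


def twonn_mu(points: PointCloud, metric: str = "euclidean") -> MuSample:
    """Compute the TWO-NN ratios mu = r2/r1 for every distinct point.

    Exact duplicates are collapsed to one representative before the
    neighbor search and the number dropped is recorded. Neighbor ties are
    broken deterministically by point index.
    """
    coords, n_dropped = _collapse_duplicates(points.coords)
    n = coords.shape[0]
    if n < 3:
        raise DegenerateCloudError(
            f"need at least 3 distinct points for TWO-NN, got {n}"
        )
    dists = cdist(coords, coords, metric=metric)
    np.fill_diagonal(dists, np.inf)
    # stable argsort → ties resolved by index order
    order = np.argsort(dists, axis=1, kind="stable")
    rows = np.arange(n)
    r1 = dists[rows, order[:, 0]]
    r2 = dists[rows, order[:, 1]]
    if np.any(r1 <= 0):
        raise DegenerateCloudError(
            "zero first-neighbor distance between distinct coordinates "
            f"under metric {metric!r}"
        )
    return MuSample(mu=r2 / r1, n_used=n, n_dropped_duplicates=n_dropped,
                    r1=r1, r2=r2)


def twonn_mle(mu: MuSample) -> IDEstimate:
    """Maximum-likelihood TWO-NN estimate d = n / sum(ln mu_i)."""
    log_sum = float(np.log(mu.mu).sum())
    if log_sum <= 0.0:
        raise EstimatorError(
            "zero log-sum: every mu equals 1, dimension undefined"
        )
    value = mu.n_used / log_sum
    return IDEstimate(
        value=value,
        method="twonn_mle",
        n_points=mu.n_used,
        diagnostics={
            "log_mu_sum": log_sum,
            "n_dropped_duplicates": mu.n_dropped_duplicates,
        },
    )


def twonn_cdf_fit(
    mu: MuSample,
    discard_fraction: float = 0.1,
    cdf_convention: str = "rank_over_n_plus_1",
) -> IDEstimate:
    """TWO-NN estimate from an origin-constrained fit of the empirical CDF.

    mu values are sorted ascending and assigned empirical CDF values
    F_i = i/(n+1) (default convention; ``rank_over_n`` uses i/n and drops
    the last point where ln(1-F) diverges). The top
    ``ceil(discard_fraction * n)`` ratios — the tail most sensitive to
    density inhomogeneity — are discarded, and d minimizes
    sum(( -ln(1-F_i) - d ln mu_i )^2), i.e. d = sum(x y)/sum(x^2) with
    x = ln mu, y = -ln(1-F).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise EstimatorError("discard_fraction must lie in [0, 1)")
    mu_sorted = np.sort(mu.mu)
    n = mu_sorted.size
    if cdf_convention == "rank_over_n_plus_1":
        f = np.arange(1, n + 1) / (n + 1)
    elif cdf_convention == "rank_over_n":
        f = np.arange(1, n + 1) / n
        mu_sorted, f = mu_sorted[:-1], f[:-1]
    else:
        raise EstimatorError(f"unknown CDF convention {cdf_convention!r}")
    n_drop = math.ceil(discard_fraction * mu_sorted.size)
    if n_drop:
        mu_sorted, f = mu_sorted[:-n_drop], f[:-n_drop]
    if mu_sorted.size < 2:
        raise EstimatorError(
            f"only {mu_sorted.size} points left after discarding "
            f"{n_drop}: need at least 2 for the CDF fit"
        )
    x = np.log(mu_sorted)
    y = -np.log1p(-f)
    sxx = float(x @ x)
    if sxx <= 0.0:
        raise EstimatorError(
            "zero log-sum: every mu equals 1, dimension undefined"
        )
    slope = float(x @ y) / sxx
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float((y**2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return IDEstimate(
        value=slope,
        method="twonn_cdf",
        n_points=mu.n_used,
        diagnostics={
            "slope": slope,
            "r_squared": r_squared,
            "discard_fraction": discard_fraction,
            "n_fit": int(mu_sorted.size),
            "cdf_convention": cdf_convention,
            "n_dropped_duplicates": mu.n_dropped_duplicates,
        },
    )


def _covariance_eigenvalues(points: PointCloud) -> np.ndarray:
    coords = points.coords
    n = coords.shape[0]
    if n < 2:
        raise DegenerateCloudError("need at least 2 points for a covariance")
    centered = coords - coords.mean(axis=0)
    # singular values of centered data give eigenvalues without forming
    # the m x m covariance (m can be the full gene repertoire)
    s = np.linalg.svd(centered, compute_uv=False)
    lam = s**2 / (n - 1)
    if lam.sum() <= 0.0:
        raise EstimatorError("zero total variance: all points identical")
    return lam


def pca_id(points: PointCloud, variance_threshold: float = 0.9) -> IDEstimate:
    """Smallest k whose top-k covariance eigenvalues reach the threshold."""
    if not 0.0 < variance_threshold <= 1.0:
        raise EstimatorError("variance_threshold must lie in (0, 1]")
    lam = _covariance_eigenvalues(points)
    frac = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    return IDEstimate(
        value=float(k),
        method="pca_variance",
        n_points=points.n_points,
        diagnostics={
            "eigenvalues": lam,
            "variance_threshold": variance_threshold,
        },
    )


def pca_participation_ratio(points: PointCloud) -> IDEstimate:
    """Participation ratio (sum l)^2 / sum(l^2) of covariance eigenvalues."""
    lam = _covariance_eigenvalues(points)
    value = float(lam.sum() ** 2 / (lam**2).sum())
    return IDEstimate(
        value=value,
        method="pca_pr",
        n_points=points.n_points,
        diagnostics={"eigenvalues": lam},
    )


def _twonn_mle_entry(points, metric="euclidean"):
    return twonn_mle(twonn_mu(points, metric=metric))


def _twonn_cdf_entry(points, metric="euclidean", **params):
    return twonn_cdf_fit(twonn_mu(points, metric=metric), **params)


ESTIMATOR_METHODS = {
    "twonn_mle": _twonn_mle_entry,
    "twonn_cdf": _twonn_cdf_entry,
    "pca_variance": pca_id,
    "pca_pr": pca_participation_ratio,
}


def estimate_id(points: PointCloud, method: str = "twonn_cdf", **params) -> IDEstimate:
    """Dispatch to a named estimator, recording method and params."""
    try:
        fn = ESTIMATOR_METHODS[method]
    except KeyError:
        raise EstimatorError(
            f"unknown estimator {method!r}; choose from "
            f"{sorted(ESTIMATOR_METHODS)}"
        ) from None
    est = fn(points, **params)
    est.diagnostics.setdefault("params", dict(params))
    return est
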
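"""Per-cell local intrinsic dimension and pseudotime root selection.

Each cell gets a "local" ID: the TWO-NN estimate on the sub-cloud formed by
the cell and its k nearest neighbors (default k = 70) in a user-supplied
coordinate space — typically a low-dimensional embedding computed upstream,
but full relative-abundance profiles work too. Local IDs are min-max
rescaled into [0, 1] across cells; the cell with the maximum local ID marks
the least differentiated region and is proposed as the root for pseudotime
inference. An externally computed pseudotime can be correlated against the
local score as a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .errors import AlignmentError, ConfigError, DegenerateCloudError, EstimatorError
from .id_estimators import PointCloud, estimate_id

__all__ = ["LocalIDResult", "local_id_scores", "select_root",
           "correlate_with_pseudotime"]


@dataclass
class LocalIDResult:
    cell_ids: np.ndarray
    local_id: np.ndarray
    local_score: np.ndarray
    k: int
    space_tag: str
    root_cell: str
    tie_flag: bool


def local_id_scores(
    points: PointCloud,
    k: int = 70,
    estimator: str = "twonn_cdf",
    space_tag: str = "embedding",
    allow_small_k: bool = False,
    estimator_params: dict | None = None,
) -> LocalIDResult:
    """Estimate a local ID on every cell's (k+1)-point neighborhood.

    The sub-cloud contains the focal cell plus its k nearest neighbors
    (exact search, ties broken by index). Neighborhoods that collapse to
    fewer than 3 distinct coordinates get NaN. k below 10 makes the
    estimator unstable and is refused unless ``allow_small_k``.
    """
    n = points.n_points
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of cells {n}")
    if k < 10 and not allow_small_k:
        raise ConfigError(
            f"k={k} below 10 makes local TWO-NN unstable; "
            "pass allow_small_k=True to override"
        )
    estimator_params = dict(estimator_params or {})
    ids = (
        points.point_ids
        if points.point_ids is not None
        else np.array([f"cell{i}" for i in range(n)], dtype=object)
    )
    dists = cdist(points.coords, points.coords)
    np.fill_diagonal(dists, np.inf)
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    local = np.empty(n)
    for i in range(n):
        sub = points.coords[np.concatenate(([i], order[i]))]
        try:
            local[i] = estimate_id(
                PointCloud(sub), estimator, **estimator_params
            ).value
        except (DegenerateCloudError, EstimatorError):
            local[i] = np.nan
    finite = np.isfinite(local)
    if not finite.any():
        raise DegenerateCloudError("every neighborhood was degenerate")
    lo, hi = np.nanmin(local), np.nanmax(local)
    if hi > lo:
        score = (local - lo) / (hi - lo)
    else:
        score = np.where(finite, 0.0, np.nan)
    root, tie = _argmax_cell(ids, local)
    return LocalIDResult(
        cell_ids=ids,
        local_id=local,
        local_score=score,
        k=k,
        space_tag=space_tag,
        root_cell=root,
        tie_flag=tie,
    )


def _argmax_cell(ids: np.ndarray, values: np.ndarray) -> tuple[str, bool]:
    top = np.nanmax(values)
    winners = sorted(str(c) for c in ids[values == top])
    return winners[0], len(winners) > 1


def select_root(result: LocalIDResult) -> str:
    """Cell attaining the maximum local ID (lexicographic tie-break)."""
    root, _ = _argmax_cell(result.cell_ids, result.local_id)
    return root


def correlate_with_pseudotime(
    result: LocalIDResult, pseudotime: pd.Series
) -> float:
    """Pearson correlation between the local ID-score and a pseudotime.

    ``pseudotime`` is indexed by cell id and must cover exactly the cells in
    ``result``. With a well-chosen root, potency decreases along pseudotime
    so a strongly negative correlation is expected.
    """
    cells = [str(c) for c in result.cell_ids]
    missing = [c for c in cells if c not in pseudotime.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} cells missing from pseudotime, "
            f"first: {missing[:5]}"
        )
    pt = pseudotime.loc[cells].to_numpy(dtype=float)
    finite = np.isfinite(result.local_score) & np.isfinite(pt)
    r, _ = pearsonr(result.local_score[finite], pt[finite])
    return float(r)
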
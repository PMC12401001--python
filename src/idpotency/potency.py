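"""The ID-score: per-group intrinsic dimension as a cell-potency measure.

All ID estimators drift with sample size in the undersampled regime typical
of scRNA-seq, so raw per-group estimates are not comparable when groups
differ in size. Comparability is restored by estimating every group at the
same matched size — a fixed fraction (default 75%) of the least represented
group — over several random subsamples (default 10), reporting mean and
standard deviation per group, and finally min-max rescaling the means into
a [0, 1] ID-score across groups. Higher score = higher inferred potency.

Two literature comparators are included for benchmarking: per-cell Shannon
entropy of the expression profile and the per-cell number of expressed
genes. They are computed independently of the ID-score and may disagree
with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateRangeError, GroupTooSmallError
from .id_estimators import PointCloud, estimate_id
from .io_formats import CountMatrix, ExpressionMatrix

__all__ = [
    "GroupIDResult",
    "IDScoreTable",
    "RankResult",
    "subsampled_group_ids",
    "rescale_scores",
    "rank_groups",
    "shannon_entropy_score",
    "expressed_gene_count",
]


@dataclass
class GroupIDResult:
    group: str
    n_cells: int
    subsample_size: int
    replicate_ids: np.ndarray
    mean_id: float = field(init=False)
    std_id: float = field(init=False)

    def __post_init__(self):
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=float)
        self.mean_id = float(self.replicate_ids.mean())
        self.std_id = float(self.replicate_ids.std())


@dataclass
class IDScoreTable:
    """Per-group mean/std IDs with [0,1] scores and run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass
class RankResult:
    order: list
    tie_groups: list


def _resolve_groups(expr: ExpressionMatrix, groups) -> np.ndarray:
    if groups is None:
        if expr.group is None:
            raise GroupTooSmallError("no group labels supplied or attached")
        return expr.group
    if isinstance(groups, pd.Series):
        missing = [c for c in expr.cell_ids if c not in groups.index]
        if missing:
            raise GroupTooSmallError(
                f"{len(missing)} cells missing from group annotation"
            )
        return groups.loc[list(expr.cell_ids)].to_numpy(dtype=object)
    labels = np.asarray(groups, dtype=object)
    if len(labels) != expr.n_cells:
        raise GroupTooSmallError("one group label per cell required")
    return labels


def subsampled_group_ids(
    expr: ExpressionMatrix,
    groups=None,
    estimator: str = "twonn_cdf",
    fraction: float = 0.75,
    n_rep: int = 10,
    seed: int = 0,
    estimator_params: dict | None = None,
) -> list[GroupIDResult]:
    """Estimate each group's ID at a matched subsample size, with replicates.

    The common subsample size is floor(fraction * size of smallest group);
    each replicate draws that many cells without replacement from its group,
    using a deterministic per-(group, replicate) substream of ``seed`` (so
    results do not depend on the order groups appear in the annotation).
    """
    labels = _resolve_groups(expr, groups)
    estimator_params = dict(estimator_params or {})
    names = sorted(set(labels))
    if len(names) < 2:
        raise GroupTooSmallError("need at least 2 groups to compare IDs")
    sizes = {g: int((labels == g).sum()) for g in names}
    for g, s in sizes.items():
        if s < 4:
            raise GroupTooSmallError(
                f"group {g!r} has only {s} cells (minimum 4)"
            )
    subsample_size = math.floor(fraction * min(sizes.values()))
    if subsample_size < 3:
        raise GroupTooSmallError(
            f"subsample size {subsample_size} too small for TWO-NN; "
            "raise the fraction or supply larger groups"
        )
    results = []
    for gi, g in enumerate(names):
        idx = np.flatnonzero(labels == g)
        # canonical member order by cell id: results must not depend on the
        # order cells appear in the input matrix
        idx = idx[np.argsort(expr.cell_ids[idx].astype(str), kind="stable")]
        reps = np.empty(n_rep)
        for r in range(n_rep):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(gi, r))
            )
            chosen = rng.choice(idx, size=subsample_size, replace=False)
            cloud = PointCloud(expr.values[chosen])
            reps[r] = estimate_id(cloud, estimator, **estimator_params).value
        results.append(
            GroupIDResult(
                group=g,
                n_cells=sizes[g],
                subsample_size=subsample_size,
                replicate_ids=reps,
            )
        )
    return results


def rescale_scores(
    results: list[GroupIDResult], metadata: dict | None = None
) -> IDScoreTable:
    """Min-max rescale per-group mean IDs to a [0, 1] score.

    Standard deviations are divided by the same range so error bars stay
    commensurate with the score. With fewer than two distinct means the
    score is undefined: a DegenerateRangeError carrying the raw results is
    raised so callers can still report unscaled IDs.
    """
    means = np.array([r.mean_id for r in results])
    lo, hi = means.min(), means.max()
    if len(results) < 2 or hi == lo:
        raise DegenerateRangeError(
            "degenerate range: need >= 2 groups with distinct mean IDs "
            "to rescale; raw IDs attached",
            results=results,
        )
    rng_width = hi - lo
    rows = [
        {
            "group": r.group,
            "n_cells": r.n_cells,
            "subsample_size": r.subsample_size,
            "mean_id": r.mean_id,
            "std_id": r.std_id,
            "score": (r.mean_id - lo) / rng_width,
            "scaled_std": r.std_id / rng_width,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    return IDScoreTable(table=table, metadata=dict(metadata or {}))


def rank_groups(table: IDScoreTable) -> RankResult:
    """Order groups by descending score (highest = most potent).

    Ties are broken lexicographically by group name and reported.
    """
    df = table.table.sort_values(
        ["score", "group"], ascending=[False, True], kind="stable"
    )
    dup = df["score"].duplicated(keep=False)
    ties = sorted(df.loc[dup, "group"].tolist())
    return RankResult(order=df["group"].tolist(), tie_groups=ties)


def shannon_entropy_score(expr: ExpressionMatrix) -> np.ndarray:
    """Per-cell Shannon entropy (bits) of the relative-abundance profile."""
    p = expr.values
    logs = np.zeros_like(p)
    np.log2(p, out=logs, where=p > 0)
    return -(p * logs).sum(axis=1)


def expressed_gene_count(cm: CountMatrix) -> np.ndarray:
    """Per-cell number of genes with nonzero counts."""
    return cm.detected_genes().astype(int)
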
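"""Thresholded gene-gene correlation networks.

A coarse, global readout of transcriptional coordination: build the network
whose nodes are genes and whose edges link pairs with Pearson correlation
magnitude at or above a threshold. As gene regulation constrains expression
onto lower-dimensional manifolds during differentiation, pairwise
correlations strengthen, so the network is expected to grow as the
intrinsic dimension falls. Both the edge count and the number of connected
(degree >= 1) genes are reported, the two natural readings of "network
size".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .io_formats import ExpressionMatrix

__all__ = ["CorrelationNetworkSummary", "correlation_network_size"]


@dataclass
class CorrelationNetworkSummary:
    threshold: float
    n_genes_considered: int
    n_edges: int
    n_connected_genes: int
    n_zero_variance_excluded: int = 0
    signed: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def correlation_network_size(
    expr: ExpressionMatrix,
    gene_subset=None,
    threshold: float = 0.7,
    signed: bool = False,
    top_genes: int | None = None,
) -> CorrelationNetworkSummary:
    """Count edges and connected genes of the thresholded correlation graph.

    Pearson correlation is computed across cells for every gene pair; an
    undirected edge is drawn where |r| >= threshold (or r >= threshold with
    ``signed=True``). Genes with zero variance across cells are excluded
    (their correlation is undefined) and the exclusion count reported.
    ``top_genes`` optionally restricts to the most variable genes to bound
    the quadratic cost on large matrices.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must lie strictly between 0 and 1")
    values = expr.values
    genes = np.asarray(expr.gene_ids, dtype=object)
    if values.shape[0] < 3:
        raise ConfigError("need at least 3 cells for gene correlations")
    if gene_subset is not None:
        wanted = set(gene_subset)
        mask = np.array([g in wanted for g in genes])
        if not mask.any():
            raise ConfigError("gene_subset does not intersect the matrix")
        values, genes = values[:, mask], genes[mask]
    variances = values.var(axis=0)
    nonzero = variances > 0
    n_zero = int((~nonzero).sum())
    values, genes, variances = values[:, nonzero], genes[nonzero], variances[nonzero]
    if values.shape[1] == 0:
        raise ConfigError("no genes with nonzero variance to correlate")
    if top_genes is not None and values.shape[1] > top_genes:
        keep = np.sort(np.argsort(variances, kind="stable")[::-1][:top_genes])
        values, genes = values[:, keep], genes[keep]
    corr = np.corrcoef(values, rowvar=False)
    strength = corr if signed else np.abs(corr)
    iu = np.triu_indices(strength.shape[0], k=1)
    edge_mask = strength[iu] >= threshold
    n_edges = int(edge_mask.sum())
    adj = np.zeros_like(strength, dtype=bool)
    adj[iu[0][edge_mask], iu[1][edge_mask]] = True
    degree = adj.sum(axis=0) + adj.sum(axis=1)
    return CorrelationNetworkSummary(
        threshold=threshold,
        n_genes_considered=int(values.shape[1]),
        n_edges=n_edges,
        n_connected_genes=int((degree > 0).sum()),
        n_zero_variance_excluded=n_zero,
        signed=signed,
    )
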
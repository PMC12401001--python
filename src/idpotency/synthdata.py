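"""Synthetic data with known intrinsic-dimension ground truth.

Two families of fixtures:

* **Manifold samples** for estimator validation: points drawn on a latent
  d-dimensional manifold (hypercube, Gaussian, hypersphere surface, swiss
  roll), rotated into a higher-dimensional ambient space by a random
  orthogonal map, optionally with isotropic noise. Unions of separated
  manifolds exercise the composite-manifold behavior of the estimators.

* **Planted differentiation hierarchies** for end-to-end pipeline tests:
  groups of cells whose expression profiles live on latent manifolds of
  decreasing dimension with depth (progenitors high-dimensional, leaves
  low-dimensional), pushed into gene space by a smooth softplus-linear map,
  then sampled as counts — Poisson by default, with heterogeneous
  log-normal library sizes and a dedicated mitochondrial gene block so
  every preprocessing stage is exercised. The planted depth order is the
  ground truth a potency score must recover.

All randomness flows from one master seed through named substreams so each
stage (maps, latent draws, library sizes, count sampling) is independently
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .id_estimators import PointCloud
from .io_formats import CountMatrix

__all__ = [
    "ManifoldSpec",
    "GroupSpec",
    "SyntheticHierarchySpec",
    "SyntheticDataset",
    "sample_manifold",
    "sample_composite",
    "generate_hierarchy",
    "default_hierarchy_spec",
]

_MANIFOLD_KINDS = ("hypercube", "hypersphere_surface", "gaussian", "swiss_roll")


@dataclass
class ManifoldSpec:
    kind: str
    latent_dim: int
    n_points: int
    embed_dim: int
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _MANIFOLD_KINDS:
            raise ConfigError(
                f"unknown manifold kind {self.kind!r}; choose from "
                f"{_MANIFOLD_KINDS}"
            )
        if self.kind == "swiss_roll" and self.latent_dim != 2:
            raise ConfigError("swiss_roll has latent dimension 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")


def _source_dim(spec: ManifoldSpec) -> int:
    # dimension of the space the raw generator lives in (before embedding)
    if spec.kind == "hypersphere_surface":
        return spec.latent_dim + 1
    if spec.kind == "swiss_roll":
        return 3
    return spec.latent_dim


def sample_manifold(spec: ManifoldSpec) -> tuple[PointCloud, int]:
    """Draw points on the named manifold and embed them in ``embed_dim``.

    Returns the cloud and the ground-truth intrinsic dimension. When the
    ambient dimension equals the source dimension and noise is zero, the
    coordinates are exactly the latent sample (identity embedding).
    """
    src = _source_dim(spec)
    if spec.embed_dim < src:
        raise ConfigError(
            f"embed_dim {spec.embed_dim} smaller than the manifold's "
            f"ambient source dimension {src}"
        )
    ss = np.random.SeedSequence(spec.seed)
    rng_latent = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    rng_map = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    rng_noise = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    del ss
    n, d = spec.n_points, spec.latent_dim
    if spec.kind == "hypercube":
        latent = rng_latent.uniform(0.0, 1.0, size=(n, d))
    elif spec.kind == "gaussian":
        latent = rng_latent.normal(size=(n, d))
    elif spec.kind == "hypersphere_surface":
        raw = rng_latent.normal(size=(n, d + 1))
        latent = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    else:  # swiss_roll
        t = rng_latent.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
        height = rng_latent.uniform(0.0, 10.0, size=n)
        latent = np.column_stack([t * np.cos(t), height, t * np.sin(t)])
    if spec.embed_dim == src:
        coords = latent
    else:
        gauss = rng_map.normal(size=(spec.embed_dim, src))
        q, r = np.linalg.qr(gauss)
        q *= np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
        coords = latent @ q.T
    if spec.noise_sd > 0:
        coords = coords + rng_noise.normal(
            0.0, spec.noise_sd, size=(n, spec.embed_dim)
        )
    return PointCloud(coords), d


def sample_composite(
    specs: list[ManifoldSpec], offsets
) -> tuple[PointCloud, np.ndarray]:
    """Union of manifold samples translated by per-component offsets.

    Returns the pooled cloud and a per-point component label (index into
    ``specs``). Overlapping supports are only warned about — estimator
    behavior on touching manifolds is a legitimate stress test.
    """
    if len(specs) < 2:
        raise ConfigError("composite needs at least 2 components")
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape[0] != len(specs):
        raise ConfigError("one offset per component required")
    clouds, labels = [], []
    for i, spec in enumerate(specs):
        cloud, _ = sample_manifold(spec)
        clouds.append(cloud.coords + offsets[i])
        labels.append(np.full(spec.n_points, i))
    coords = np.vstack(clouds)
    labels = np.concatenate(labels)
    _warn_on_overlap(clouds)
    return PointCloud(coords), labels


def _warn_on_overlap(clouds):
    for i in range(len(clouds)):
        for j in range(i + 1, len(clouds)):
            lo_i, hi_i = clouds[i].min(axis=0), clouds[i].max(axis=0)
            lo_j, hi_j = clouds[j].min(axis=0), clouds[j].max(axis=0)
            if np.all(hi_i >= lo_j) and np.all(hi_j >= lo_i):
                warnings.warn(
                    f"bounding boxes of components {i} and {j} overlap; "
                    "supports may not be separated",
                    stacklevel=3,
                )
                return


@dataclass
class GroupSpec:
    name: str
    depth: int
    latent_dim: int
    n_cells: int


@dataclass
class SyntheticHierarchySpec:
    """Planted differentiation hierarchy in gene space.

    Latent dimension must strictly decrease with depth: the deeper
    (more differentiated) a group, the fewer effective degrees of freedom
    its expression manifold has. Defaults emulate a deeply sequenced
    full-length (read-count) experiment: ~1e6 counts per cell (log-normal,
    sigma 0.25) over 2000 genes with a Zipf-like heavy-tailed baseline
    (log-rate sd 2.5) and a 5% mitochondrial block. Sequencing depth must
    resolve the lowest-dimensional manifold at nearest-neighbor scale for
    the planted order to be recoverable; shallow-depth regimes can be
    emulated by lowering ``library_log_mean``.
    """

    groups: list[GroupSpec]
    n_genes: int = 2000
    library_log_mean: float = math.log(1_000_000.0)
    library_log_sd: float = 0.25
    baseline_log_sd: float = 2.5
    signal_amplitude: float = 3.0
    mito_fraction: float = 0.05
    n_mito_genes: int = 13
    mito_prefix: str = "MT-"
    group_offset_sd: float = 0.3
    nonlinearity: str = "softplus"
    counts_model: str = "poisson"
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) < 1:
            raise ConfigError("at least one group required")
        by_depth = sorted(self.groups, key=lambda g: g.depth)
        for a, b in zip(by_depth, by_depth[1:]):
            if b.latent_dim >= a.latent_dim:
                raise ConfigError(
                    "latent_dim must strictly decrease with depth "
                    f"({a.name}: d={a.latent_dim} at depth {a.depth}, "
                    f"{b.name}: d={b.latent_dim} at depth {b.depth})"
                )
        for g in self.groups:
            if g.n_cells < 20:
                raise ConfigError(
                    f"group {g.name!r} needs at least 20 cells"
                )
        d_max = max(g.latent_dim for g in self.groups)
        if self.n_genes < 4 * d_max:
            raise ConfigError(
                f"n_genes={self.n_genes} too small to preserve latent "
                f"dimension {d_max}; need at least {4 * d_max}"
            )
        if not 0.0 <= self.mito_fraction < 1.0:
            raise ConfigError("mito_fraction must lie in [0, 1)")
        if self.nonlinearity != "softplus":
            raise ConfigError("only the softplus nonlinearity is implemented")
        if self.counts_model not in ("poisson", "negative_binomial"):
            raise ConfigError(
                "counts_model must be poisson or negative_binomial"
            )


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    truth: pd.DataFrame  # columns: group, depth, latent_dim, n_cells
    config: dict = field(default_factory=dict)


def default_hierarchy_spec(seed: int = 0, n_cells: int = 300) -> SyntheticHierarchySpec:
    """Reference three-level hierarchy: root d=15, mid d=8, leaf d=3."""
    return SyntheticHierarchySpec(
        groups=[
            GroupSpec("root", 0, 15, n_cells),
            GroupSpec("mid", 1, 8, n_cells),
            GroupSpec("leaf", 2, 3, n_cells),
        ],
        seed=seed,
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_hierarchy(spec: SyntheticHierarchySpec) -> SyntheticDataset:
    """Sample a count matrix from the planted hierarchy.

    Per group g with latent dimension d_g: latent coordinates z uniform in
    [0,1]^{d_g}; per-gene rates softplus(A_g z + b + c_g) with a shared
    heavy-tailed baseline b, a small group offset c_g, and nested loadings
    A_g — the first d_g columns of one shared loading matrix, scaled by
    signal_amplitude/sqrt(d_g). Nesting encodes differentiation as the
    progressive loss of variation directions, and the 1/sqrt(d) column
    scale keeps every gene's signal variance independent of the group's
    latent dimension. Rates are normalized per cell, with a fixed
    ``mito_fraction`` of the rate mass routed to the mitochondrial gene
    block; counts are drawn as Poisson(rate * library size) with
    log-normal library sizes (or gamma-Poisson when
    ``counts_model='negative_binomial'``).
    """
    rng_maps = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    rng_latent = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    rng_library = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    rng_sampling = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(3,)))
    rng_mito = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(4,)))

    n_expr = spec.n_genes - spec.n_mito_genes
    if n_expr <= 0:
        raise ConfigError("n_genes must exceed n_mito_genes")
    baseline = rng_maps.normal(0.0, spec.baseline_log_sd, size=n_expr)
    d_max = max(g.latent_dim for g in spec.groups)
    shared_loadings = rng_maps.normal(0.0, 1.0, size=(n_expr, d_max))
    mito_profile = rng_mito.dirichlet(np.ones(spec.n_mito_genes))

    blocks, labels, cell_ids = [], [], []
    offset = 0
    for g in spec.groups:
        # nested maps: each group varies along the first d_g shared
        # directions; the 1/sqrt(d) column scale keeps per-gene signal
        # variance independent of the group's latent dimension
        loadings = shared_loadings[:, : g.latent_dim] * (
            spec.signal_amplitude / math.sqrt(g.latent_dim)
        )
        group_shift = (
            rng_maps.normal(0.0, spec.group_offset_sd, size=n_expr)
            if spec.group_offset_sd > 0
            else 0.0
        )
        z = rng_latent.uniform(0.0, 1.0, size=(g.n_cells, g.latent_dim))
        rates = _softplus(z @ loadings.T + baseline + group_shift)
        rates /= rates.sum(axis=1, keepdims=True)
        rates *= 1.0 - spec.mito_fraction
        mito = np.tile(spec.mito_fraction * mito_profile, (g.n_cells, 1))
        full = np.hstack([mito, rates])
        libs = rng_library.lognormal(
            spec.library_log_mean, spec.library_log_sd, size=g.n_cells
        )
        lam = full * libs[:, None]
        if spec.counts_model == "poisson":
            counts = rng_sampling.poisson(lam)
        else:
            shape = spec.nb_dispersion
            lam = rng_sampling.gamma(shape, lam / shape)
            counts = rng_sampling.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        labels.extend([g.name] * g.n_cells)
        cell_ids.extend(
            f"{g.name}_cell{offset + i:05d}" for i in range(g.n_cells)
        )
        offset += g.n_cells

    gene_ids = [f"{spec.mito_prefix}{i + 1}" for i in range(spec.n_mito_genes)]
    gene_ids += [f"GENE{i + 1:05d}" for i in range(n_expr)]
    cm = CountMatrix(
        sp.vstack(blocks).tocsr(),
        np.asarray(cell_ids, dtype=object),
        np.asarray(gene_ids, dtype=object),
        np.asarray(labels, dtype=object),
    )
    truth = pd.DataFrame(
        [
            {
                "group": g.name,
                "depth": g.depth,
                "latent_dim": g.latent_dim,
                "n_cells": g.n_cells,
            }
            for g in spec.groups
        ]
    )
    config = {
        "n_genes": spec.n_genes,
        "library_log_mean": spec.library_log_mean,
        "library_log_sd": spec.library_log_sd,
        "baseline_log_sd": spec.baseline_log_sd,
        "signal_amplitude": spec.signal_amplitude,
        "mito_fraction": spec.mito_fraction,
        "n_mito_genes": spec.n_mito_genes,
        "group_offset_sd": spec.group_offset_sd,
        "counts_model": spec.counts_model,
        "seed": spec.seed,
    }
    return SyntheticDataset(counts=cm, truth=truth, config=config)
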
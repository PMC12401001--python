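import math
import warnings

import numpy as np
import pytest

from idpotency.errors import ConfigError, EmptyFilterError
from idpotency.id_estimators import PointCloud, estimate_id
from idpotency.io_formats import CellFilterSpec, filter_cells, normalize_relative
from idpotency.potency import subsampled_group_ids
from idpotency.synthdata import (
    GroupSpec,
    ManifoldSpec,
    SyntheticHierarchySpec,
    generate_hierarchy,
    sample_composite,
    sample_manifold,
)


class TestManifoldSampling:
    def test_identity_embedding_when_minimal_and_noiseless(self):
        cloud, d = sample_manifold(ManifoldSpec("hypercube", 4, 100, 4, seed=0))
        assert d == 4
        assert cloud.coords.shape == (100, 4)
        assert cloud.coords.min() >= 0.0 and cloud.coords.max() <= 1.0

    def test_sphere_surface_has_unit_norms(self):
        cloud, d = sample_manifold(
            ManifoldSpec("hypersphere_surface", 2, 50, 3, seed=1)
        )
        assert d == 2
        assert np.allclose(np.linalg.norm(cloud.coords, axis=1), 1.0)

    def test_embedding_dimension_below_source_rejected(self):
        with pytest.raises(ConfigError, match="smaller"):
            sample_manifold(ManifoldSpec("hypercube", 5, 100, 3, seed=0))
        with pytest.raises(ConfigError, match="smaller"):
            sample_manifold(ManifoldSpec("swiss_roll", 2, 100, 2, seed=0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError, match="kind"):
            ManifoldSpec("torus", 2, 100, 3, seed=0)

    def test_rotated_hypercube_recovers_its_dimension(self):
        cloud, _ = sample_manifold(ManifoldSpec("hypercube", 5, 2000, 40, seed=0))
        assert estimate_id(cloud, "twonn_cdf").value == pytest.approx(5, rel=0.15)

    def test_gaussian_participation_ratio_matches_latent_dim(self):
        cloud, _ = sample_manifold(ManifoldSpec("gaussian", 3, 2000, 50, seed=2))
        assert estimate_id(cloud, "pca_pr").value == pytest.approx(3, rel=0.10)

    def test_swiss_roll_reads_as_a_surface(self):
        cloud, d = sample_manifold(ManifoldSpec("swiss_roll", 2, 2000, 5, seed=3))
        assert d == 2
        assert estimate_id(cloud, "twonn_cdf").value == pytest.approx(2, rel=0.2)

    def test_seed_determinism(self):
        spec = ManifoldSpec("gaussian", 4, 50, 10, noise_sd=0.1, seed=9)
        a, _ = sample_manifold(spec)
        b, _ = sample_manifold(spec)
        assert np.array_equal(a.coords, b.coords)


class TestCompositeSampling:
    @staticmethod
    def _mixture(seed=1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sample_composite(
                [
                    ManifoldSpec("hypercube", 2, 500, 10, seed=seed),
                    ManifoldSpec("hypercube", 10, 500, 10, seed=seed + 1),
                ],
                offsets=[np.zeros(10), np.full(10, 30.0)],
            )

    def test_labels_partition_the_union(self):
        cloud, labels = self._mixture()
        assert cloud.coords.shape == (1000, 10)
        assert list(np.bincount(labels)) == [500, 500]

    def test_per_component_dimensions_recovered(self):
        cloud, labels = self._mixture()
        for comp, d in ((0, 2), (1, 10)):
            est = estimate_id(
                PointCloud(cloud.coords[labels == comp]), "twonn_cdf"
            )
            assert est.value == pytest.approx(d, rel=0.2)

    def test_single_component_rejected(self):
        with pytest.raises(ConfigError, match="2 components"):
            sample_composite(
                [ManifoldSpec("hypercube", 2, 100, 2, seed=0)],
                offsets=[np.zeros(2)],
            )

    def test_overlapping_supports_only_warn(self):
        specs = [
            ManifoldSpec("hypercube", 3, 50, 3, seed=0),
            ManifoldSpec("gaussian", 2, 50, 3, seed=1),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            sample_composite(specs, offsets=[np.zeros(3), np.zeros(3)])

    def test_union_estimate_sits_below_the_arithmetic_mean(self):
        """The pooled estimate on a 2-d + 10-d union is pulled well below
        the arithmetic mean of the component dimensions."""
        cloud, _ = self._mixture(seed=7)
        value = estimate_id(cloud, "twonn_cdf").value
        assert value < 4.5  # far below mean(2, 10) = 6


class TestHierarchyGeneration:
    def test_counts_are_deterministic_in_the_seed(self):
        spec = SyntheticHierarchySpec(
            groups=[GroupSpec("a", 0, 6, 25), GroupSpec("b", 1, 3, 25)],
            n_genes=100,
            seed=4,
        )
        x = generate_hierarchy(spec)
        y = generate_hierarchy(spec)
        assert (x.counts.counts != y.counts.counts).nnz == 0
        assert list(x.counts.cell_ids) == list(y.counts.cell_ids)

    def test_labels_and_truth_cover_all_groups(self, small_hierarchy):
        ds = small_hierarchy
        assert set(ds.counts.group) == {"prog", "diff"}
        assert set(ds.truth["group"]) == {"prog", "diff"}
        assert ds.truth.set_index("group").loc["prog", "latent_dim"] == 8

    def test_mito_block_carries_the_target_fraction(self, small_hierarchy):
        frac = small_hierarchy.counts.mito_fraction("MT-")
        assert frac.mean() == pytest.approx(0.05, abs=0.01)

    def test_high_mito_fixture_trips_the_filter(self):
        spec = SyntheticHierarchySpec(
            groups=[GroupSpec("a", 0, 6, 25), GroupSpec("b", 1, 3, 25)],
            n_genes=100,
            mito_fraction=0.5,
            seed=0,
        )
        ds = generate_hierarchy(spec)
        with pytest.raises(EmptyFilterError):
            filter_cells(ds.counts, CellFilterSpec(0, 0, 0.1))

    def test_latent_dims_must_strictly_decrease_with_depth(self):
        with pytest.raises(ConfigError, match="strictly decrease"):
            SyntheticHierarchySpec(
                groups=[GroupSpec("a", 0, 5, 25), GroupSpec("b", 1, 5, 25)],
                n_genes=100,
            )

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigError, match="20 cells"):
            SyntheticHierarchySpec(
                groups=[GroupSpec("a", 0, 5, 10), GroupSpec("b", 1, 3, 25)],
                n_genes=100,
            )

    def test_gene_space_must_preserve_dimension(self):
        with pytest.raises(ConfigError, match="too small"):
            SyntheticHierarchySpec(
                groups=[GroupSpec("a", 0, 30, 25), GroupSpec("b", 1, 3, 25)],
                n_genes=100,
            )

    def test_planted_order_recovered_through_scoring(self, small_hierarchy):
        expr = normalize_relative(small_hierarchy.counts)
        results = {
            r.group: r.mean_id
            for r in subsampled_group_ids(expr, n_rep=3, seed=0)
        }
        assert results["prog"] > results["diff"]

    def test_library_scale_invariance_of_group_ids(self):
        """A tenfold change in sequencing depth barely moves group IDs:
        relative-abundance normalization absorbs it."""
        def mean_ids(log_mean):
            spec = SyntheticHierarchySpec(
                groups=[GroupSpec("a", 0, 8, 60), GroupSpec("b", 1, 3, 60)],
                n_genes=400,
                library_log_mean=log_mean,
                seed=0,
            )
            expr = normalize_relative(generate_hierarchy(spec).counts)
            return {
                r.group: r.mean_id
                for r in subsampled_group_ids(expr, n_rep=3, seed=0)
            }

        base = mean_ids(math.log(1e6))
        deep = mean_ids(math.log(1e7))
        for g in base:
            assert deep[g] == pytest.approx(base[g], rel=0.10)

    def test_negative_binomial_counts_available(self):
        spec = SyntheticHierarchySpec(
            groups=[GroupSpec("a", 0, 6, 25), GroupSpec("b", 1, 3, 25)],
            n_genes=100,
            counts_model="negative_binomial",
            seed=2,
        )
        ds = generate_hierarchy(spec)
        assert ds.counts.counts.min() >= 0
        assert ds.config["counts_model"] == "negative_binomial"
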
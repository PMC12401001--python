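import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from idpotency.io_formats import CountMatrix
from idpotency.synthdata import (
    GroupSpec,
    SyntheticHierarchySpec,
    default_hierarchy_spec,
    generate_hierarchy,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 cells x 4 genes with a mito gene, hand-checkable totals."""
    counts = np.array(
        [
            [5, 0, 2, 1],   # cellA: total 8, 3 genes, mito 1/8
            [0, 3, 0, 0],   # cellB: total 3, 1 gene, mito 0
            [10, 10, 10, 30],  # cellC: total 60, 4 genes, mito 30/60
        ]
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        ["cellA", "cellB", "cellC"],
        ["g1", "g2", "g3", "MT-g4"],
    )


@pytest.fixture(scope="session")
def small_hierarchy():
    """Two-level planted hierarchy kept small enough for unit tests."""
    spec = SyntheticHierarchySpec(
        groups=[GroupSpec("prog", 0, 8, 60), GroupSpec("diff", 1, 3, 60)],
        n_genes=400,
        seed=11,
    )
    return generate_hierarchy(spec)


@pytest.fixture(scope="session")
def reference_hierarchy():
    """The reference root/mid/leaf dataset (seed 0)."""
    return generate_hierarchy(default_hierarchy_spec(seed=0))
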
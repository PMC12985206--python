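import numpy as np
import pytest

from pathfuse.model import ModelConfig, StagingFusionModel
from pathfuse.synthetic import SyntheticSpec, make_toy_hierarchy, simulate_cohort


@pytest.fixture(scope="session")
def default_world():
    """The stated synthetic world: 400 samples, 500 genes, one expression driver."""
    spec = SyntheticSpec(seed=1)
    hierarchy, membership, relations = make_toy_hierarchy(spec)
    cohort = simulate_cohort(spec, hierarchy)
    return spec, hierarchy, cohort


@pytest.fixture(scope="session")
def fitted_results(default_world):
    """One cross-validated fit of the default world, shared by expensive tests."""
    _, hierarchy, cohort = default_world
    model = StagingFusionModel.from_cohort(cohort, hierarchy, ModelConfig(seed=0))
    results = model.fit(k=5, seed=0)
    return model, results


@pytest.fixture()
def tiny_world():
    """A 60-sample, 40-gene world for fast structural tests."""
    spec = SyntheticSpec(
        n_samples=60, n_genes=40, n_leaf_pathways=4, genes_per_pathway=10,
        n_levels=2, leaves_per_parent=2, seed=3,
        driver_pathways=[("LP01", "expression", 3.0)],
    )
    hierarchy, membership, relations = make_toy_hierarchy(spec)
    cohort = simulate_cohort(spec, hierarchy)
    return spec, hierarchy, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
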
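import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rs_stages import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    PlantedSet,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"N{i}" for i in range(4)] + [f"T{i}" for i in range(4)]
    return ExpressionMatrix(genes, samples, rng.normal(8, 1, size=(20, 8)))


@pytest.fixture
def small_labels(small_expr):
    return PhenotypeLabels(small_expr.sample_ids, [0, 0, 0, 0, 1, 1, 1, 1])


@pytest.fixture
def small_sets(small_expr):
    g = small_expr.gene_ids
    return GeneSetCollection({"a": g[:5], "b": g[5:12], "c": g[12:]})


@pytest.fixture
def planted_dataset():
    """G=500 dataset with one strongly up-planted and one down-planted set."""
    cfg = SimulationConfig(
        G=500,
        n_normal=15,
        n_tumor=15,
        n_sets=12,
        set_size_range=(10, 50),
        planted=[PlantedSet(0, "up", 2.0, 1.0), PlantedSet(1, "down", 2.0, 1.0)],
        seed=11,
    )
    return generate_dataset(cfg)
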
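import numpy as np
import pytest

from ifcstate import FeatureTable, PopulationSpec, generate_population


@pytest.fixture
def tiny_labeled_table() -> FeatureTable:
    """Four cells, two features, two balanced classes."""
    return FeatureTable(
        values=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0], [6.0, 7.0]]),
        feature_names=["area", "intensity"],
        sample_ids=["c0", "c1", "c2", "c3"],
        labels=np.array(["viable", "viable", "apoptotic", "apoptotic"], dtype=object),
    )


@pytest.fixture
def separable_population() -> FeatureTable:
    """Well-separated two-class population, 400 cells, 10 features."""
    return generate_population(
        PopulationSpec(
            m=400,
            n_informative=3,
            n_redundant=2,
            n_noise=5,
            separation=4.0,
            seed=42,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
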
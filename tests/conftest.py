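import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hergml.lb_features import compute_lb_features
from hergml.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort small enough for unit tests."""
    return generate_cohort(GeneratorConfig(n_compounds=300, seed=11))


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return small_cohort.labels


@pytest.fixture(scope="session")
def small_lb_matrix(small_cohort):
    pairs = list(
        zip(small_cohort.compounds["compound_id"], small_cohort.compounds["smiles"])
    )
    return compute_lb_features(pairs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
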
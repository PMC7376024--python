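import pytest
from dataclasses import replace

from serometa.preprocess import (
    filter_missingness,
    impute_minimum,
    quantile_normalize,
    scale_metabolites,
)
from serometa.synthetic_data import CohortSimulator, SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact null cohort config: 10 groups x 10 metabolites, no effects."""
    return replace(
        SimConfig(),
        n_metabolites=100,
        n_groups=10,
        special_groups=(),
        planted_logfc=(),
        planted_cross=(),
    )


@pytest.fixture(scope="session")
def small_simulator(small_config) -> CohortSimulator:
    return CohortSimulator(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_simulator):
    """One censored cohort draw: (matrix, metadata, annotation, truth)."""
    return small_simulator.generate(7)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (118 x 946, planted effects, censored)."""
    return CohortSimulator(SimConfig()).generate(3)


def preprocess_chain(matrix):
    """filter -> impute -> quantile normalize -> scale."""
    filtered, _ = filter_missingness(matrix)
    normalized = quantile_normalize(impute_minimum(filtered))
    return normalized, scale_metabolites(normalized)


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    matrix, metadata, annotation, truth = small_cohort
    _, scaled = preprocess_chain(matrix)
    return scaled, metadata, annotation
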
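import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

from stimulome import RobustICA, SyntheticDesign, center_to_reference, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """A compact planted design shared across decomposition tests."""
    return SyntheticDesign(
        n_genes=500,
        n_components=5,
        n_conditions=8,
        n_batch_conditions=3,
        replicates_per_condition=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design, seed=11)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    X, truth = small_dataset
    Xc = center_to_reference(X, X.samples_where(phase="batch"))
    results = RobustICA(Xc, dimensionality=truth.n_components, n_restarts=6).fit(11)
    return Xc, truth, results
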
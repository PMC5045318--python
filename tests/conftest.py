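import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coffee_truth():
    from genoverlap.synthetic import default_twin_truth

    return default_twin_truth("coffee")


@pytest.fixture(scope="session")
def coffee_sample(coffee_truth):
    """One simulated twin sample at the coffee-variant generating truth."""
    from genoverlap.synthetic import simulate_twin_sample
    from genoverlap.twin_model import TwinData

    params, thresholds, design = coffee_truth
    records = simulate_twin_sample(params, thresholds, design, rng=np.random.default_rng(7))
    return records, TwinData.from_records(records)


@pytest.fixture(scope="session")
def coffee_ae_fit(coffee_sample):
    """A converged AE fit on the shared coffee sample, reused across tests."""
    from genoverlap.twin_model import fit_model

    _, data = coffee_sample
    fit = fit_model(data, model="AE", seed=3)
    assert fit.converged
    return fit
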
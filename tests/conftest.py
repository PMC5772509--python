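import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario, shared read-only across tests."""
    from c3iso.synthetic_data import generate_scenario

    return generate_scenario(seed=0)


@pytest.fixture()
def flat_noisy_series():
    """Irregular series with constant truth and honest 1-sigma errors."""
    rng = np.random.default_rng(42)
    ages = np.sort(rng.uniform(0.0, 30.0, 120))
    return pd.DataFrame(
        {
            "age_kyr_bp": ages,
            "value": 240.0 + rng.normal(0, 2.0, ages.size),
            "sigma": 2.0,
            "outlier": False,
        }
    )
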
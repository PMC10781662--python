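import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pcorona as pc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset() -> pc.CoronaDataset:
    """Hand-built 4-row table: 2 categorical, 2 numerical factors, 2 proteins."""
    factors = pd.DataFrame(
        {
            "np_type": ["silica", "metal", "silica", "polymer"],
            "medium": ["water", "PBS", "PBS", "water"],
            "size_nm": [50.0, 120.0, 80.0, 200.0],
            "zeta_mv": [-30.0, 10.0, -5.0, 25.0],
        }
    )
    rpa = pd.DataFrame({"P01": [0.5, 1.2, 0.8, 4.0], "P02": [2.0, 0.1, 0.3, 0.9]})
    kinds = {"np_type": "categorical", "medium": "categorical",
             "size_nm": "numerical", "zeta_mv": "numerical"}
    return pc.CoronaDataset(factors=factors, rpa=rpa, factor_kinds=kinds)


@pytest.fixture(scope="session")
def synth_small():
    """A reduced synthetic dataset shared by model-level tests."""
    config = pc.SyntheticConfig(n_rows=200, n_proteins=4, seed=11)
    dataset, truth = pc.generate_dataset(config)
    return dataset, truth


@pytest.fixture
def skewed_targets() -> np.ndarray:
    rng = np.random.default_rng(7)
    return rng.lognormal(mean=0.0, sigma=1.0, size=400)
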
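import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nddprs.config import SimConfig
from nddprs.simulate import simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-size cohort: full study structure, small panel."""
    return SimConfig(n_variants=800, n_blocks=40, n_genes=600,
                     n_de_genes=60, seed=1)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def nineteen_samples() -> pd.DataFrame:
    """A 19-patient sample sheet with the study's 9/10 group split."""
    r = np.random.default_rng(7)
    ids = [f"p{i:02d}" for i in range(19)]
    return pd.DataFrame({
        "id": ids,
        "group": ["high"] * 9 + ["low"] * 10,
        "sex": r.choice(["M", "F"], size=19),
        "age": r.integers(40, 90, size=19),
    })
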
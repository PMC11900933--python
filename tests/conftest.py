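import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def default_cohort():
    from epiaging import generate_cohort

    return generate_cohort(seed=0)


@pytest.fixture
def cohort_csv(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    default_cohort.to_csv(path, index=False)
    return path
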
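import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import ednadetect as ed


@pytest.fixture(scope="session")
def pond_study():
    return ed.builtin_pond_study()


@pytest.fixture(scope="session")
def stocked(pond_study):
    return ed.subset(pond_study, predicate=lambda d: d["pond_id"] != 1)


@pytest.fixture(scope="session")
def control(pond_study):
    return ed.subset(pond_study, pond_id=1)


@pytest.fixture(scope="session")
def std():
    return ed.study_standardization()


@pytest.fixture(scope="session")
def fast_cfg():
    """Short chains for unit tests that only need a rough posterior."""
    return ed.MCMCConfig(iterations=4000, burn_in=1000, chains=2, seed=7)


@pytest.fixture(scope="session")
def best_fit(stocked, std):
    """Shared fit of the top-ranked model (intercept, middle, density,
    temperature) to the stocked-pond samples, at a desk-scale profile."""
    spec = ed.ModelSpec(fixed_terms=("density", "temperature", "middle"))
    cfg = ed.MCMCConfig(iterations=10_000, burn_in=2_500, chains=3, seed=11)
    return ed.fit(stocked, spec, std, cfg)
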
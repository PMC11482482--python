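import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ablasim as ab

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_result() -> ab.CaseResult:
    """Full phantom baseline at default resolution: 35 W, 600 s, 7 degC coolant."""
    return ab.run_case(ab.CaseConfig.phantom())


@pytest.fixture(scope="session")
def coarse_phantom_config() -> ab.CaseConfig:
    from dataclasses import replace

    cfg = ab.CaseConfig.phantom()
    return replace(
        cfg,
        grid_policy=ab.GridPolicy.coarse(),
        thermal=replace(cfg.thermal, duration=120.0, snapshot_interval=2.0),
    )


@pytest.fixture(scope="session")
def coarse_phantom_result(coarse_phantom_config) -> ab.CaseResult:
    """Reduced-resolution short phantom run for plumbing-level tests."""
    return ab.run_case(coarse_phantom_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240930)
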
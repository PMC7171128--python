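import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from gbmgrowth.reference import (
    PUBLISHED_MEAN_SURFACE,
    PUBLISHED_SD_SURFACE,
    SEATTLE_RECORDS,
    TRONDHEIM_PARAMS,
    WAITING_TIME_GRID,
)
from gbmgrowth.survival_calc import SurvivalSurfaces, build_fpt_grid

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """SDE constants fitted to the Trondheim cohort."""
    return TRONDHEIM_PARAMS


@pytest.fixture(scope="session")
def zero_noise_params():
    """Deterministic (c = 0) limit of the fitted model."""
    return dataclasses.replace(TRONDHEIM_PARAMS, c=0.0)


@pytest.fixture(scope="session")
def published_surfaces():
    """The published mean/SD waiting-time surfaces."""
    return SurvivalSurfaces(mean=PUBLISHED_MEAN_SURFACE, sd=PUBLISHED_SD_SURFACE)


@pytest.fixture(scope="session")
def table4():
    """The 39 printed waiting-time grid cells."""
    return list(WAITING_TIME_GRID)


@pytest.fixture(scope="session")
def seattle():
    return list(SEATTLE_RECORDS)


@pytest.fixture(scope="session")
def mc_grid_500():
    """A 500-path waiting-time grid simulated once and shared across tests."""
    return build_fpt_grid(TRONDHEIM_PARAMS, n_paths=500, step=0.05, seed=123)
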
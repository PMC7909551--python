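import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amikpk import (
    AssayErrorModel,
    CovariateModel,
    DoseEvent,
    ParametricPopulation,
    PKParams,
    TDMDesign,
    simulate_tdm_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def typical_params() -> PKParams:
    """Final-model typical subject: CL 2.25 L/h, V 18 L."""
    return PKParams(CLs=2.25, V=18.0)


@pytest.fixture
def single_800mg() -> list[DoseEvent]:
    return [DoseEvent(start_time=0.0, amount=800.0, infusion_duration=0.5)]


@pytest.fixture
def error_model() -> AssayErrorModel:
    return AssayErrorModel()


@pytest.fixture
def population() -> ParametricPopulation:
    return ParametricPopulation()


@pytest.fixture
def rich_design() -> TDMDesign:
    """Two doses, eight samples: identifies CL and V per subject."""
    return TDMDesign(
        n_doses=2,
        sample_offsets_h=(0.75, 1.0, 2.0, 4.0, 8.0, 12.0, 23.5, 25.0),
    )


@pytest.fixture
def sparse_design() -> TDMDesign:
    """Peak/trough sampling emulating routine monitoring."""
    return TDMDesign()


@pytest.fixture
def small_cohort(population, rich_design, error_model):
    return simulate_tdm_cohort(population, 8, rich_design, error_model, seed=11)


@pytest.fixture
def covariate_model() -> CovariateModel:
    return CovariateModel()
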
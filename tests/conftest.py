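import pytest
from hypothesis import HealthCheck, settings

from ammoflux import CellModel, SensitivityBox
from ammoflux.io import load_reference_observations

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model() -> CellModel:
    return CellModel.default()


@pytest.fixture(scope="session")
def default_box() -> SensitivityBox:
    return SensitivityBox()


@pytest.fixture(scope="session")
def reference_observations():
    return load_reference_observations()


@pytest.fixture(scope="session")
def reference_by_key(reference_observations):
    return {(o.strain, o.ph_ec): o for o in reference_observations}
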
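"""Shared fixtures and hypothesis configuration for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ikirspan import BodyWaterModel, LabelingProtocol

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def protocol() -> LabelingProtocol:
    return LabelingProtocol()


@pytest.fixture()
def water(protocol: LabelingProtocol) -> BodyWaterModel:
    return BodyWaterModel(f=0.02, delta=0.06, protocol=protocol)
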
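"""Shared fixtures. Session-scoped toy bodies are cached by the fixtures
module; tests that mutate a model must copy it first."""

import pytest
from hypothesis import HealthCheck, settings

import wholebody as wb

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    return wb.make_toy_body(0)


@pytest.fixture(scope="session")
def toy_fragile():
    return wb.make_toy_body(0, "fragile")


@pytest.fixture(scope="session")
def toy_redundant():
    return wb.make_toy_body(0, "redundant")


@pytest.fixture(scope="session")
def constrained(toy):
    return toy.constrained_model()
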
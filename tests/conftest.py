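"""Shared fixtures: a small simulated genome and library."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ohm import simulate as sim

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    return sim.simulate_genome({"chr2": 3_000_000, "chr3": 4_000_000}, 5.0, seed=0)


@pytest.fixture(scope="session")
def small_model():
    return sim.SimModel(seed=42)


@pytest.fixture(scope="session")
def small_library(small_genome, small_model):
    """200k-pair library with its ground truth (shared, treat as read-only)."""
    return sim.simulate_library(small_genome, small_model, 200_000)
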
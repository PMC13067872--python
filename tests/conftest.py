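"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from revlink.model import ModelParameters, SystemTopology


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_mixture() -> SystemTopology:
    """A small A/B mixture in a cubic box, suitable for second-scale runs."""
    return SystemTopology.preset(NA=7, nA=20, nB=3, box=(12.0, 12.0, 12.0))
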
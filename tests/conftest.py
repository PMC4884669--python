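"""Shared fixtures: reference model objects and expensive session-scoped runs."""

from __future__ import annotations

import numpy as np
import pytest

from placentaflux import PlacentaModel, reference_parameters
from placentaflux.fitting import fit_activities


@pytest.fixture()
def reference():
    """(geometry, params, inputs, initial) reference tuple."""
    return reference_parameters()


@pytest.fixture()
def model():
    """Full-scenario model at the physiological reference."""
    return PlacentaModel()


@pytest.fixture(scope="session")
def reference_steady():
    """Steady-state result of the full reference scenario (computed once)."""
    return PlacentaModel().steady_state_result()


@pytest.fixture(scope="session")
def literature_fit():
    """Activity fit against the published umbilical V−A targets (computed once)."""
    return fit_activities(PlacentaModel())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160328)
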
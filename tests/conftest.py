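"""Shared fixtures: small synthetic scans and reconstruction scaffolding."""

from __future__ import annotations

import numpy as np
import pytest

from radarperm import (
    DASReconstructor,
    GridSpec,
    Phantom,
    Pulse,
    Scatterer,
    circular_array,
    simulate_scan,
    subtract_calibration,
    suppress_skin,
)
from radarperm.io import fixture_phantom, make_fixture_scan


@pytest.fixture(scope="session")
def single_phantom() -> Phantom:
    return fixture_phantom("single_scatterer")


@pytest.fixture(scope="session")
def noiseless_scan(single_phantom):
    """Noise-free scan of the single-scatterer phantom, 20 antennas."""
    array = circular_array(20, 52.0)
    return simulate_scan(single_phantom, array, Pulse(), seed=0, noise_level=0.0)


@pytest.fixture(scope="session")
def processed_scan(noiseless_scan):
    """Calibrated and skin-suppressed noise-free scan."""
    return suppress_skin(subtract_calibration(noiseless_scan))


@pytest.fixture(scope="session")
def reconstructor(processed_scan, single_phantom):
    return DASReconstructor(processed_scan, GridSpec(extent=50.0, spacing=1.0),
                            single_phantom)


@pytest.fixture(scope="session")
def fixture_scan_seed0():
    """The canonical single-scatterer fixture (default seed, mild noise)."""
    scan, truth = make_fixture_scan("single_scatterer", seed=0)
    return scan, truth
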
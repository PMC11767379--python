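"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from evophase.lattice import UnitCell, build_grid
from evophase.synthetic import ToyCrystalSpec, generate_toy_crystal


@pytest.fixture(scope="session")
def toy_bundle():
    """The reference toy crystal: P1, 72% solvent, noiseless amplitudes."""
    return generate_toy_crystal(ToyCrystalSpec(seed=3))


@pytest.fixture(scope="session")
def small_grid_spec():
    """A small cubic grid for cheap Fourier tests."""
    return build_grid(UnitCell(16.0, 16.0, 16.0), 4.0, 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
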
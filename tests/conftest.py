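"""Shared fixtures: small geometries for unit tests and one full-size
phantom study reused by the expensive end-to-end checks."""

import numpy as np
import pytest

from qsmcalc.core_io import AcquisitionProtocol, Mask, ScalarVolume, VoxelGrid
from qsmcalc.pipeline import PipelineConfig, run_phantom_study


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture()
def small_grid():
    """Isotropic 1 mm grid centred on the world origin."""
    return VoxelGrid((48, 40, 32), (1.0, 1.0, 1.0), origin_mm=(-23.5, -19.5, -15.5))


@pytest.fixture()
def container_geometry(protocol):
    """Container-scale geometry for background-removal oracles: a box ROI
    with room for the 1-25 mm kernel family, sources inside and outside."""
    grid = VoxelGrid((96, 96, 56), (1.5, 1.5, 2.5), origin_mm=(-71.25, -71.25, -68.75))
    x, y, z = grid.coordinate_arrays()
    mask = Mask(grid, (np.abs(x) <= 55) & (np.abs(y) <= 55) & (np.abs(z) <= 50))
    return grid, mask


@pytest.fixture(scope="session")
def phantom_study():
    """Full-size noise-free five-sphere study (the expensive fixture).

    Session-scoped: simulation + both-segmentation metrics at the default
    192x192x64 grid, shared by every end-to-end assertion.
    """
    config = PipelineConfig()
    report = run_phantom_study(config, seed=1)
    return config, report


def wrap_phase(p):
    return np.mod(p + np.pi, 2.0 * np.pi) - np.pi
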
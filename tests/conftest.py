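"""Shared fixtures: desk-scale scanner, trajectory, tracer, and system matrix.

The heavy objects (trajectory, system matrix) are session-scoped: every test
that exercises the reconstruction chain reuses one deterministic build.
"""

from __future__ import annotations

import numpy as np
import pytest

from fflsim import (TracerModel, make_sequence, build_system_matrix,
                    ReconGrid, default_recon_params)
from fflsim.presets import desk_scale, DESK_RECON_PIXEL

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def config():
    return desk_scale()


@pytest.fixture(scope="session")
def tracer():
    return TracerModel()


@pytest.fixture(scope="session")
def trajectory(config):
    traj, _ = make_sequence(config)
    return traj


@pytest.fixture(scope="session")
def waveforms(config):
    _, wf = make_sequence(config)
    return wf


@pytest.fixture(scope="session")
def band(config):
    return default_recon_params(config)


@pytest.fixture(scope="session")
def recon_grid(config):
    return ReconGrid.cover(config.fov_x, config.fov_z, DESK_RECON_PIXEL,
                           margin=0.15)


@pytest.fixture(scope="session")
def system_matrix(config, tracer, recon_grid, band):
    return build_system_matrix(config, tracer, recon_grid, 0.15, params=band)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
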
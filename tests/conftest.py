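"""Shared fixtures: a coarse phantom scene reused across the suite.

All fixtures are generated programmatically — nothing is read from disk —
and every stochastic fixture is seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from tartrack.phantom import PhantomConfig, build_phantom, synthesize_gait_trajectory

#: Coarse, fast phantom used by most structural tests.
COARSE = dict(spacing_mm=1.5, arc_points=17, mesh_layers=7, tube_sections=24,
              frame_rate_hz=30.0)


@pytest.fixture(scope="session")
def coarse_config():
    return PhantomConfig(**COARSE)


@pytest.fixture(scope="session")
def coarse_scene(coarse_config):
    scene, _volume = build_phantom(coarse_config, seed=0)
    return scene


@pytest.fixture(scope="session")
def coarse_volume(coarse_scene):
    return coarse_scene.volume


@pytest.fixture(scope="session")
def coarse_trajectory(coarse_scene):
    return synthesize_gait_trajectory(coarse_scene, seed=1,
                                      n_stance_frames=24, frame_rate_hz=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
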
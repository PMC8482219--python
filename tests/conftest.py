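"""Shared simulation fixtures.

Sessions are simulated once per test session; tests must not mutate them.
"""

from dataclasses import replace

import numpy as np
import pytest

import gazekit as gk


@pytest.fixture(scope="session")
def scene():
    """The simulated-study scene: eye at (0, 200, 550) mm, 400x300 mm screen."""
    return gk.default_scene()


@pytest.fixture(scope="session")
def scene_kappa0(scene):
    """Same scene with a kappa-free eye (optical axis == visual axis)."""
    return replace(scene, eye=replace(scene.eye, kappa=(0.0, 0.0)))


@pytest.fixture(scope="session")
def led_scene():
    return gk.default_scene(with_leds=True)


@pytest.fixture(scope="session")
def calib21():
    return gk.calibration_indices(21, 21)


@pytest.fixture(scope="session")
def aligned_session(scene):
    """Camera aligned with the eyeball/screen center at the screen plane."""
    return gk.simulate_session(scene.with_camera_at((0.0, 200.0, 0.0)), (21, 21))


@pytest.fixture(scope="session")
def offaxis_session(scene):
    """Strongly off-axis camera (the skewed-distribution example pose)."""
    return gk.simulate_session(scene.with_camera_at((-250.0, 400.0, 0.0)), (21, 21))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210941)
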
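"""Shared fixtures: geometries and reusable reconstructed scenes.

Expensive holographic chains are session-scoped so several tests can share
one simulation.
"""

import numpy as np
import pytest

import holoqpi as h
from holoqpi.qpi import PMMA_IN_GLYCEROL_WATER
from holoqpi.reconstruct import demodulate

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def cfg1024():
    return h.default_geometry()


@pytest.fixture(scope="session")
def cfg512():
    return h.default_geometry(sensor_pixels=512)


@pytest.fixture(scope="session")
def cfg256():
    return h.default_geometry(sensor_pixels=256)


@pytest.fixture(scope="session")
def bead_material():
    return PMMA_IN_GLYCEROL_WATER


@pytest.fixture(scope="session")
def sphere512(cfg512, bead_material):
    """9.8 µm PMMA bead transmittance and thickness truth on a 512 grid."""
    obj, thick = h.sphere_transmittance(
        cfg512, radius=4.9e-6, delta_n=bead_material.delta_n
    )
    return obj, thick


@pytest.fixture(scope="session")
def blank512(cfg512):
    return h.blank_hologram(cfg512)


@pytest.fixture(scope="session")
def blank512_demod(blank512):
    return demodulate(blank512)


@pytest.fixture(scope="session")
def sphere512_recon(cfg512, sphere512, blank512):
    """Noise-free off-axis recording and full reconstruction of the bead."""
    obj, thick = sphere512
    holo = h.record_hologram(obj, cfg512)
    q = h.reconstruct_hologram(holo, blank=blank512, unwrap=True)
    truth_phase = 2 * np.pi * 0.036 / cfg512.wavelength * thick
    return holo, q, truth_phase
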
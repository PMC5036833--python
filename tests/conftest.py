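"""Shared fixtures.

The resolution sweeps are expensive (30 renderings each), so they are
session-scoped and shared between the module tests and the acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import cineshear as cs


@pytest.fixture(scope="session")
def cca_geometry():
    return cs.cca_like()


@pytest.fixture(scope="session")
def ica_geometry():
    return cs.ica_like()


@pytest.fixture(scope="session")
def carotid_wave():
    return cs.carotid_waveform()


@pytest.fixture(scope="session")
def steady_series(cca_geometry):
    """Noise-free steady 2.7 mL/s rendering at 0.2 mm (2 frames)."""
    acq = cs.AcquisitionSpec(pixel_spacing=0.2, frame_duration=500.0, snr=None)
    return cs.render_series(cca_geometry, cs.steady_waveform(2.7), acq)


@pytest.fixture(scope="session")
def fine_pulsatile_series(cca_geometry, carotid_wave):
    """Noise-free carotid-like rendering at 0.2 mm / 24.4 ms."""
    acq = cs.AcquisitionSpec(pixel_spacing=0.2, frame_duration=24.4, snr=None)
    return cs.render_series(cca_geometry, carotid_wave, acq)


def true_circle_mask(series, radius):
    """Pixels whose centres lie inside the centred circle of ``radius`` mm."""
    x, y = series.pixel_centers()
    cx, cy = x.mean(), y.mean()
    xg, yg = np.meshgrid(x - cx, y - cy, indexing="xy")
    return np.hypot(xg, yg) <= radius


@pytest.fixture(scope="session")
def cca_sweep_noise_free(cca_geometry, carotid_wave):
    """Noise-free per-measurement sweep over the 30-pair protocol grid."""
    acq = cs.AcquisitionSpec(pixel_spacing=1.0, frame_duration=100.0, snr=None)
    records = cs.run_sweep(
        cca_geometry, carotid_wave, segmentation="per-measurement", seed=7, acq=acq
    )
    assert len(records) == 30
    return records


@pytest.fixture(scope="session")
def cca_sweep_best_noise_free(cca_geometry, carotid_wave):
    """Noise-free sweep reusing the finest-grid ("best") contour."""
    acq = cs.AcquisitionSpec(pixel_spacing=1.0, frame_duration=100.0, snr=None)
    records = cs.run_sweep(cca_geometry, carotid_wave, segmentation="best", seed=7, acq=acq)
    assert len(records) == 30
    return records


@pytest.fixture(scope="session")
def ica_sweep_noise_free(ica_geometry, carotid_wave):
    """Noise-free per-measurement sweep of the skewed-profile section."""
    acq = cs.AcquisitionSpec(pixel_spacing=1.0, frame_duration=100.0, snr=None)
    records = cs.run_sweep(
        ica_geometry, carotid_wave, segmentation="per-measurement", seed=11, acq=acq
    )
    assert len(records) == 30
    return records
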
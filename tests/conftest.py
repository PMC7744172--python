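"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (explicit loops,
direct formula evaluation) and independent of the package code paths they
validate.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from lightcore.phantom import (
    AcquisitionGeometry,
    BiopsyPhantom,
    NOISELESS,
    NoiseParams,
)

# ---------------------------------------------------------------------------
# geometry oracles


def trilinear_oracle(vol: np.ndarray, z: float, y: float, x: float) -> float:
    """Direct trilinear interpolation at node-centred index coordinates.

    Voxel ``(i, j, k)`` sits at index position ``(i, j, k)``; outside the
    grid the value is 0.
    """
    nz, ny, nx = vol.shape
    val = 0.0
    z0, y0, x0 = math.floor(z), math.floor(y), math.floor(x)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                zi, yi, xi = z0 + dz, y0 + dy, x0 + dx
                w = ((1 - abs(z - zi)) * (1 - abs(y - yi))
                     * (1 - abs(x - xi)))
                if w <= 0:
                    continue
                if 0 <= zi < nz and 0 <= yi < ny and 0 <= xi < nx:
                    val += w * vol[zi, yi, xi]
    return val


def brute_force_frames(phantom: BiopsyPhantom, geometry: AcquisitionGeometry,
                       n_frames: int, attenuation_length: float = math.inf
                       ) -> np.ndarray:
    """Re-evaluate the oblique forward mapping pixel by pixel.

    Frame k, row r, col c samples the phantom at
    ``x = k*s + r*p*cos(theta)``, ``y = c*p``, ``z = r*p*sin(theta)``.
    """
    p = geometry.binned_pitch
    theta = math.radians(geometry.sheet_angle)
    s = geometry.frame_interval_um
    rows, cols = geometry.frame_shape
    v = phantom.voxel_pitch
    out = np.zeros((n_frames, rows, cols))
    for k in range(n_frames):
        for r in range(rows):
            z_um = r * p * math.sin(theta)
            att = math.exp(-z_um / attenuation_length) \
                if math.isfinite(attenuation_length) else 1.0
            for c in range(cols):
                x_um = k * s + r * p * math.cos(theta)
                y_um = c * p
                out[k, r, c] = att * trilinear_oracle(
                    phantom.volume, z_um / v, y_um / v, x_um / v)
    return out


def delta_phantom(shape: tuple[int, int, int], voxel_pitch: float,
                  source_zyx: tuple[int, int, int],
                  intensity: float = 1000.0) -> BiopsyPhantom:
    """A phantom that is zero except for a single bright voxel."""
    vol = np.zeros(shape)
    vol[source_zyx] = intensity
    nz, ny, nx = shape
    return BiopsyPhantom(
        volume=vol,
        labels=np.zeros(shape, dtype=np.uint8),
        glands=[],
        truth_label="benign",
        voxel_pitch=voxel_pitch,
        extent=(nx * voxel_pitch, ny * voxel_pitch, nz * voxel_pitch),
        seed=0,
    )


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture()
def small_geometry() -> AcquisitionGeometry:
    """Tiny matched 45-degree geometry for fast simulation tests."""
    return AcquisitionGeometry(native_pixel_pitch=1.25, binning=1,
                               sheet_angle=45.0, roi_rows=32, roi_cols=64)


@pytest.fixture()
def noiseless() -> NoiseParams:
    return NOISELESS
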
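"""Shared fixtures: analytic surfaces with known parameter values."""

import numpy as np
import pytest

from microwear.io import HeightMap


def make_grid(n: int = 128, extent_um: float = 10.0):
    """Square pixel grid of n x n over extent_um, returning (x, y, dx)."""
    dx = extent_um / n
    y, x = np.meshgrid(np.arange(n) * dx, np.arange(n) * dx, indexing="ij")
    return x, y, dx


def cosine_ridges(lay_deg: float, wavelength_um: float = 2.5, amplitude_um: float = 0.1,
                  n: int = 256, extent_um: float = 10.0, phase: float = 0.7) -> HeightMap:
    """Pure sinusoidal ridge field with crests along ``lay_deg``."""
    x, y, dx = make_grid(n, extent_um)
    normal = np.deg2rad(lay_deg + 90.0)
    proj = x * np.cos(normal) + y * np.sin(normal)
    z = amplitude_um * np.cos(2 * np.pi * proj / wavelength_um + phase)
    return HeightMap(z, dx, dx)


def gaussian_bumps(centers_um, sigma_um: float = 0.5, height_um: float = 0.2,
                   n: int = 128, extent_um: float = 10.0) -> HeightMap:
    x, y, dx = make_grid(n, extent_um)
    z = np.zeros((n, n))
    for (x0, y0) in centers_um:
        z += height_um * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma_um**2))
    return HeightMap(z, dx, dx)


@pytest.fixture
def flat_map() -> HeightMap:
    return HeightMap(np.zeros((64, 64)), 10 / 64, 10 / 64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160923)
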
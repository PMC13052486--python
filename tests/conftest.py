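"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lsci.core import SpeckleFrame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from lsci.simulate import (
    DynamicsField,
    OpticalConfig,
    SimSpec,
)


def brute_force_contrast_map(pixels: np.ndarray, window_size: int = 5) -> np.ndarray:
    """Direct per-pixel std/mean loop over full windows — no convolution.

    Sample standard deviation (ddof=1); NaN in the border and in windows with
    non-positive mean.  Independent oracle for the vectorized map.
    """
    px = np.asarray(pixels, dtype=np.float64)
    half = window_size // 2
    out = np.full(px.shape, np.nan)
    for r in range(half, px.shape[0] - half):
        for c in range(half, px.shape[1] - half):
            win = px[r - half : r + half + 1, c - half : c + half + 1]
            m = win.mean()
            if m > 0:
                out[r, c] = win.std(ddof=1) / m
    return out


def measured_speckle_diameter(pixels: np.ndarray) -> float:
    """Speckle diameter from the radial width of the intensity autocovariance.

    Twice the first lag (along columns) where the normalized circular
    autocovariance drops below 5% of its zero-lag value.
    """
    c = pixels - pixels.mean()
    ac = np.fft.ifft2(np.abs(np.fft.fft2(c)) ** 2).real
    profile = ac[0, : pixels.shape[1] // 2] / ac[0, 0]
    below = np.flatnonzero(profile < 0.05)
    if below.size == 0:
        raise AssertionError("autocovariance never decays below 5%")
    k = int(below[0])
    # sub-pixel crossing by linear interpolation between lags k-1 and k
    r = k - 1 + (profile[k - 1] - 0.05) / (profile[k - 1] - profile[k])
    return 2.0 * float(r)


def uniform_tau_spec(
    grid: tuple[int, int],
    tau_c_ms: float,
    seed: int,
    n_frames: int = 1,
    beta: float = 1.0,
    speckle_size_px: float = 4.0,
    exposure_ms: float = 5.0,
) -> SimSpec:
    """SimSpec with a spatially uniform correlation time."""
    return SimSpec(
        grid_shape=grid,
        speckle_size_px=speckle_size_px,
        optics=OpticalConfig(exposure_ms=exposure_ms, coherence_factor=beta),
        dynamics=DynamicsField(np.full(grid, tau_c_ms)),
        n_frames=n_frames,
        seed=seed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_frame(rng) -> SpeckleFrame:
    """A 16x16 random-intensity frame."""
    return SpeckleFrame(pixels=rng.uniform(0.1, 1.0, (16, 16)), frame_index=0)
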
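"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from bftrack.segmentation import Detection
from bftrack.tracking import Track


# ---------------------------------------------------------------------------
# independent band-pass oracle: same mathematical definition, different code
# path (explicit shifted-sum convolution on symmetric padding, no scipy)


def oracle_gaussian_kernel(sigma: float) -> np.ndarray:
    r = int(math.ceil(4.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def oracle_boxcar_kernel(half_width: float) -> np.ndarray:
    w = 2 * int(round(half_width)) + 1
    return np.full(w, 1.0 / w)


def _oracle_conv_axis(a: np.ndarray, k: np.ndarray, axis: int) -> np.ndarray:
    # symmetric kernels make convolution == correlation, so no kernel flip
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    r = len(k) // 2
    pad = [(r, r)] + [(0, 0)] * (a.ndim - 1)
    ap = np.pad(a, pad, mode="symmetric")
    out = np.zeros_like(a, dtype=float)
    for j in range(len(k)):
        out += k[j] * ap[j : j + n]
    return np.moveaxis(out, 0, axis)


def oracle_bandpass(image: np.ndarray, noise_scale: float, object_scale: float) -> np.ndarray:
    """Direct-sum evaluation of (I*G*G) − (I*B*B) with the zeroed border."""
    img = np.asarray(image, dtype=float)
    g = oracle_gaussian_kernel(noise_scale)
    b = oracle_boxcar_kernel(object_scale)
    smooth_g = img
    smooth_b = img
    for _ in range(2):
        for axis in (0, 1):
            smooth_g = _oracle_conv_axis(smooth_g, g, axis)
            smooth_b = _oracle_conv_axis(smooth_b, b, axis)
    out = smooth_g - smooth_b
    m = int(round(object_scale))
    out[:m, :] = 0.0
    out[-m:, :] = 0.0
    out[:, :m] = 0.0
    out[:, -m:] = 0.0
    return out


# ---------------------------------------------------------------------------
# scene helpers


def render_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: float = 6.0,
    peak: float = 100.0,
) -> np.ndarray:
    """One isotropic Gaussian blob at a sub-pixel (x, y) center."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    return peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def simple_detection(frame: int, x: float, y: float, peak_value: float = 10.0,
                     area: int = 100) -> Detection:
    return Detection(
        frame_index=frame,
        centroid=(x, y),
        peak_position=(int(round(x)), int(round(y))),
        peak_value=peak_value,
        area=area,
        footprint=frozenset({(int(round(x)), int(round(y)))}),
    )


def make_track(positions, track_id: int = 0, frames=None) -> Track:
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Track(track_id=track_id, frames=frames, positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
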
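"""Shared fixtures: rasterized reference shapes and small synthetic scenes."""

import numpy as np
import pytest

from vesiclepop.synthgen import (
    PopulationParams,
    RenderParams,
    render_frame,
    sample_population,
)


def rasterize_disk(radius_px: int, shape=None) -> np.ndarray:
    """Filled disk centered on a grid (default grid pads the disk by 28 px)."""
    n = 2 * radius_px + 56 if shape is None else shape
    yy, xx = np.mgrid[:n, :n]
    c = n / 2.0
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2).astype(np.int32)


def rasterize_ellipse(a_px: float, b_px: float) -> np.ndarray:
    """Filled axis-aligned ellipse with semi-axes (a, b) in (col, row)."""
    n = int(2 * max(a_px, b_px)) + 56
    yy, xx = np.mgrid[:n, :n]
    c = n / 2.0
    return ((((yy - c) / b_px) ** 2 + ((xx - c) / a_px) ** 2) <= 1.0).astype(np.int32)


def rasterize_square(side_px: int) -> np.ndarray:
    n = side_px + 56
    out = np.zeros((n, n), dtype=np.int32)
    lo = (n - side_px) // 2
    out[lo : lo + side_px, lo : lo + side_px] = 1
    return out


def rasterize_annulus(radius_px: int, width_px: int, gap_deg: float = 0.0,
                      shape=None, center=None) -> np.ndarray:
    """Ring of given radius/width, optionally with an angular gap (degrees)."""
    n = 2 * radius_px + 40 if shape is None else shape
    yy, xx = np.mgrid[:n, :n]
    cy, cx = (n / 2.0, n / 2.0) if center is None else center
    rho = np.hypot(yy - cy, xx - cx)
    ring = np.abs(rho - radius_px) <= width_px / 2.0
    if gap_deg > 0:
        theta = np.degrees(np.arctan2(yy - cy, xx - cx))
        ring &= ~(np.abs(theta) <= gap_deg / 2.0)
    return ring


@pytest.fixture(scope="session")
def small_population():
    """60 vesicles in a small chamber; reused by render/segment tests."""
    return sample_population(
        PopulationParams(n_vesicles=60, chamber_um=(200.0, 190.5), seed=5)
    )


@pytest.fixture(scope="session")
def rendered_scene(small_population):
    """A noise-seeded rendered scene (800x762) with its ground-truth mask."""
    params = RenderParams(frame_shape=(800, 762), seed=5)
    return render_frame(small_population, (0.0, 0.0), params)
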
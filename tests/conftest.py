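import math

import numpy as np
import pytest

import retmorph as rm
from retmorph.mask import BinaryMask
from retmorph.synthetic import rasterize_tube


@pytest.fixture(scope="session")
def tree_scene():
    """One default-condition vascular tree scene (full camera frame)."""
    return rm.generate_vessel_tree(rm.VesselTreeParams(seed=3))


@pytest.fixture(scope="session")
def small_tree_params():
    """Compact tree parameters for fast pipeline-level tests."""
    return rm.VesselTreeParams(
        seed=0, image_height_px=600, image_width_px=800,
        disc_center=(300.0, 400.0), disc_diameter_px=60.0,
        n_roots=4, root_caliber_px=6.0, branch_rate=1.2,
        tortuosity_amplitude_px=2.0, max_depth=4, min_caliber_px=1.5)


@pytest.fixture(scope="session")
def y_mask():
    """Three width-7 tubes meeting at one point: 1 branch, 3 ends."""
    g = np.zeros((300, 300), dtype=bool)
    c = np.array([150.0, 150.0])
    for ang_deg in (90, 210, 330):
        a = math.radians(ang_deg)
        d = np.array([math.sin(a), math.cos(a)])
        rasterize_tube(g.shape, np.vstack([c, c + 100 * d]), 3.5, out=g)
    return BinaryMask(g)


def make_convex_blob(rng, size=90, n_pts=10):
    """Random filled convex polygon raster for disc-diameter oracles."""
    from skimage.draw import polygon
    from scipy.spatial import ConvexHull
    pts = rng.uniform(size * 0.15, size * 0.85, size=(n_pts, 2))
    hull = ConvexHull(pts)
    poly = pts[hull.vertices]
    rr, cc = polygon(poly[:, 0], poly[:, 1], shape=(size, size))
    g = np.zeros((size, size), dtype=bool)
    g[rr, cc] = True
    return BinaryMask(g)


def brute_force_min_rect_long_side(mask, step_deg=0.1):
    """Oracle: min-area rectangle long side over a fine orientation grid.

    Scans every orientation over the pixel-center cloud of all foreground
    pixels (independent of the implementation's hull-and-calipers path)
    and applies the same half-pixel-per-end padding convention.
    """
    coords = np.argwhere(mask.grid).astype(float)
    best = None
    for ang in np.arange(0.0, 90.0, step_deg):
        a = math.radians(ang)
        rot = coords @ np.array([[math.cos(a), -math.sin(a)],
                                 [math.sin(a), math.cos(a)]])
        ext = rot.max(axis=0) - rot.min(axis=0)
        area = ext[0] * ext[1]
        if best is None or area < best[0]:
            best = (area, float(max(ext)))
    return best[1] + 1.0
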
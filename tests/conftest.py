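import numpy as np
import pytest

from rbcarea import SmearImage
from rbcarea.segmentation import CellContour, ContourStatus, polygon_area
from rbcarea.synthetic import SceneSpec, generate_scene


def make_contour(points, microns_per_pixel=0.1, status=None) -> CellContour:
    """CellContour from raw polygon vertices, geometry derived on the fly."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, float)
    area_px = polygon_area(pts)
    hull = ConvexHull(pts).volume
    ct = CellContour(
        points=pts,
        area_px=area_px,
        area_um2=area_px * microns_per_pixel**2,
        convexity_ratio=min(area_px / hull, 1.0),
    )
    ct.status = status
    return ct


def circle_polygon(center, radius, n=128):
    """Regular n-gon approximating a circle, as (row, col) vertices."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(t), center[1] + radius * np.cos(t)])


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def candidate(area_um2, convexity=0.95):
    """Square candidate contour scaled to the requested calibrated area."""
    side_px = np.sqrt(area_um2) / 0.1
    pts = np.array([[0, 0], [0, side_px], [side_px, side_px], [side_px, 0]], float)
    ct = CellContour(
        points=pts,
        area_px=side_px**2,
        area_um2=area_um2,
        convexity_ratio=convexity,
    )
    ct.status = ContourStatus.CANDIDATE
    return ct


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic noise-bearing scene plus its ground truth."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture
def white_image():
    return SmearImage(
        pixels=np.full((128, 128, 3), 255, dtype=np.uint8),
        microns_per_pixel=0.1,
        source_id="white",
    )
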
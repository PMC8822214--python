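"""Per-cell area via the minimum enclosing circle and roundness recall.

For each effective single cell the smallest circle containing every
contour point is found (Welzl's randomized incremental algorithm, exact
support-point arithmetic in float64). With r the circle radius and r_i the
distance of contour point i from the circle center, the per-cell roundness
profile is the set of ratios r_i / r and Pmean their mean. A cell is a
*recall RBC* when every ratio exceeds ``roundness_min`` (default 0.85) and
the enclosing-circle area lies in the open window (a * S_mean, b * S_mean);
only recall RBCs are averaged into the smear summary.

The two area quantities are

    Si = pi * r^2            (enclosing-circle area)
    Sr = Si * Pmean^2        (roundness-corrected cell area)

Sr equals pi * (mean r_i)^2 and approximates the true disk area of a
round cell; Sr <= Si always, with equality only for a perfect circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classification import CellClass, CellRecord
from .segmentation import CellContour

__all__ = [
    "GeometryError",
    "SmearSummary",
    "min_enclosing_circle",
    "roundness_profile",
    "is_recall_rbc",
    "area_si",
    "area_sr",
    "coefficient_of_variation",
    "summarize_smear",
    "ROUNDNESS_MIN",
]

ROUNDNESS_MIN = 0.85

_EPS = 1e-10


class GeometryError(ValueError):
    """Raised for degenerate geometric input (too few or collinear points)."""


@dataclass
class SmearSummary:
    """Per-subject aggregate over measured (recall) RBCs.

    ``mean_area_um2``/``sd_area_um2``/``cv_percent`` are None when not
    defined (no cells, or a single cell for the SD/CV).
    """

    subject_id: str
    n_rbc_measured: int
    mean_area_um2: float | None
    sd_area_um2: float | None
    cv_percent: float | None


def _circle_two(p, q):
    center = (p + q) / 2.0
    return center, math.dist(p, q) / 2.0


def _circle_three(p, q, r):
    """Circumcircle of three points, or None if they are collinear."""
    (ax, ay), (bx, by), (cx, cy) = p, q, r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax), abs(ay), abs(bx), abs(by), abs(cx), abs(cy), 1.0)
    if abs(d) < _EPS * scale * scale:
        return None
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, math.dist(center, p)


def _contains(center, radius, p, tol):
    return math.dist(center, p) <= radius + tol


def _fallback_collinear(a, b, c):
    # collinear support: the diameter circle of the farthest pair covers all
    best = None
    for p, q, s in ((a, b, c), (a, c, b), (b, c, a)):
        center, radius = _circle_two(p, q)
        if _contains(center, radius, s, _EPS * (radius + 1.0)):
            if best is None or radius < best[1]:
                best = (center, radius)
    return best


def min_enclosing_circle(contour: CellContour | np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle containing every contour point.

    Welzl's move-to-front incremental construction: expected O(n), exact up
    to float64 rounding (well inside 1e-6 px for pixel-scale coordinates).

    Returns ``(center, radius_px)`` with center as a (row, col) array.

    Raises
    ------
    GeometryError
        If fewer than 3 distinct points are supplied.
    """
    pts = contour.points if isinstance(contour, CellContour) else np.asarray(contour, float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise GeometryError(f"need >= 3 distinct points, got {len(pts)}")
    # fixed-seed shuffle: randomization only drives the expected runtime
    rng = np.random.default_rng(12345)
    pts = pts[rng.permutation(len(pts))]
    scale = float(np.abs(pts).max()) + 1.0
    tol = _EPS * scale

    center, radius = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _contains(center, radius, pts[i], tol):
            continue
        # pts[i] is on the boundary of the circle of pts[:i+1]
        q = pts[i]
        center, radius = _circle_two(pts[0], q)
        for j in range(1, i):
            if _contains(center, radius, pts[j], tol):
                continue
            q2 = pts[j]
            center, radius = _circle_two(q, q2)
            for k in range(j):
                if _contains(center, radius, pts[k], tol):
                    continue
                circ = _circle_three(q, q2, pts[k])
                if circ is None:
                    circ = _fallback_collinear(q, q2, pts[k])
                center, radius = circ
    return center, float(radius)


def roundness_profile(
    contour: CellContour | np.ndarray,
    center: np.ndarray,
    radius_px: float,
) -> tuple[np.ndarray, float]:
    """Distance ratios r_i / r of contour points to the circle center.

    Returns ``(ratios, pmean)`` with every ratio in [0, 1] and pmean their
    arithmetic mean, computed per cell.
    """
    if radius_px <= 0:
        raise GeometryError(f"enclosing-circle radius must be > 0, got {radius_px}")
    pts = contour.points if isinstance(contour, CellContour) else np.asarray(contour, float)
    dists = np.linalg.norm(pts - np.asarray(center, float), axis=1)
    ratios = np.clip(dists / radius_px, 0.0, 1.0)
    return ratios, float(ratios.mean())


def is_recall_rbc(
    ratios: np.ndarray,
    area_circle_um2: float,
    s_mean_um2: float,
    a: float = 0.3,
    b: float = 5.0,
    roundness_min: float = ROUNDNESS_MIN,
) -> bool:
    """Recall check: all ratios above ``roundness_min`` and the circle area
    inside the open window (a * S_mean, b * S_mean)."""
    if s_mean_um2 <= 0:
        raise ValueError(f"S_mean must be > 0, got {s_mean_um2}")
    ratios = np.asarray(ratios, float)
    return bool(
        np.all(ratios > roundness_min)
        and a * s_mean_um2 < area_circle_um2 < b * s_mean_um2
    )


def area_si(radius_px: float, microns_per_pixel: float) -> float:
    """Enclosing-circle area Si = pi * (r * calibration)^2 in um^2."""
    if radius_px <= 0:
        raise ValueError(f"radius must be > 0, got {radius_px}")
    return math.pi * (radius_px * microns_per_pixel) ** 2


def area_sr(si_um2: float, pmean: float) -> float:
    """Roundness-corrected area Sr = Si * Pmean^2 in um^2."""
    if si_um2 <= 0:
        raise ValueError(f"Si must be > 0, got {si_um2}")
    if not (0 < pmean <= 1):
        raise ValueError(f"Pmean must be in (0, 1], got {pmean}")
    return si_um2 * pmean * pmean


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV as a percentage: 100 * SD / mean."""
    if mean == 0:
        raise ValueError("CV is undefined for zero mean")
    return 100.0 * sd / mean


def summarize_smear(
    cells: list[CellRecord], subject_id: str, include_non_recall: bool = False
) -> SmearSummary:
    """Mean, sample SD (n-1) and CV of Sr over recall RBCs.

    Cells that are not classified RBC, or that failed the roundness/range
    recall, do not contribute (unless ``include_non_recall`` admits
    non-recall RBCs whose Sr was still computed). With zero qualifying
    cells all aggregates are None; with one, SD and CV are None.
    """
    areas = np.array(
        [
            c.sr_um2
            for c in cells
            if c.cell_class is CellClass.RBC
            and (c.recall or (include_non_recall and c.sr_um2 is not None))
        ],
        dtype=float,
    )
    n = len(areas)
    if n == 0:
        return SmearSummary(subject_id, 0, None, None, None)
    mean = float(areas.mean())
    if n == 1:
        return SmearSummary(subject_id, 1, mean, None, None)
    sd = float(areas.std(ddof=1))
    return SmearSummary(subject_id, n, mean, sd, coefficient_of_variation(mean, sd))
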
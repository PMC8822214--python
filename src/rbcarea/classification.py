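"""RBC vs nucleated-cell discrimination by the gray-value ratio G / Mg.

Under Wright-Giemsa staining, nucleated cells (leukocytes, erythroid
precursors) carry a dark purple nucleus while anucleate red cells are a
uniform pale pink, so the mean gray value of an RBC is close to the
per-image mean over all located single cells (Mg) while a nucleated cell
falls well below it. A single cell with G / Mg above the ratio threshold
(default 0.8) is called an RBC, below it a nucleated cell; the exact-tie
case goes to RBC (documented half-open decision boundary, configurable).

Mg is computed once per image over the effective single cells only and the
classification is a single pass — the ratio uses the fixed Mg even though
nucleated cells themselves contribute to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.draw import polygon as draw_polygon

from .imaging import GrayImage
from .segmentation import CellContour

__all__ = [
    "CellClass",
    "CellRecord",
    "mean_gray_of_cell",
    "cohort_mean_gray",
    "classify_cell",
    "RATIO_THRESHOLD",
]

RATIO_THRESHOLD = 0.8


class CellClass(str, Enum):
    RBC = "rbc"
    NUCLEATED = "nucleated"


@dataclass
class CellRecord:
    """One located single cell with its gray ratio, class and area results.

    ``si_um2`` is the minimum-enclosing-circle area pi*r^2; ``sr_um2`` is
    the roundness-corrected area Si * Pmean^2, present only when the cell
    passed the recall (roundness + area-range) check.
    """

    contour: CellContour
    g: float
    mg: float = float("nan")
    g_ratio: float = float("nan")
    cell_class: CellClass | None = None
    circle_center: tuple[float, float] | None = None
    circle_radius_px: float = float("nan")
    pmean: float = float("nan")
    si_um2: float = float("nan")
    sr_um2: float | None = None
    recall: bool = False


def _interior_pixels(gray: GrayImage, contour: CellContour) -> np.ndarray:
    pts = contour.points
    h, w = gray.shape
    if pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5 or pts[:, 0].max() > h - 0.5 or pts[:, 1].max() > w - 0.5:
        raise ValueError("contour extends outside the image bounds")
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=gray.shape)
    return gray.pixels[rr, cc]


def mean_gray_of_cell(gray: GrayImage, contour: CellContour) -> float:
    """Mean gray value G over the pixels enclosed by the contour polygon.

    The interior is filled, so nucleus and central-pallor pixels are
    included; raises if the contour lies outside the image.
    """
    vals = _interior_pixels(gray, contour)
    if vals.size == 0:
        raise ValueError("contour encloses no pixels")
    return float(vals.mean())


def cohort_mean_gray(cells: list[CellRecord]) -> float:
    """Mg: mean of per-cell G over all located single cells in the image."""
    if not cells:
        raise ValueError("no located single cells: Mg is undefined for an empty field")
    return float(np.mean([c.g for c in cells]))


def classify_cell(g: float, mg: float, ratio_threshold: float = RATIO_THRESHOLD) -> CellClass:
    """RBC if G / Mg >= ratio_threshold, nucleated otherwise (ties -> RBC)."""
    if mg <= 0:
        raise ValueError(f"Mg must be > 0, got {mg}")
    return CellClass.RBC if g / mg >= ratio_threshold else CellClass.NUCLEATED
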
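"""Image I/O, color-space conversion and pixel/micrometer calibration.

Everything downstream measures in micrometers; the only place pixels and
micrometers meet is the ``microns_per_pixel`` calibration attached to a
:class:`SmearImage` at load time. 0.1 um/px is a typical value for a
1000x oil-immersion field captured with a standard microscope camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
from skimage import color as skcolor

__all__ = [
    "SmearImage",
    "HSVImage",
    "GrayImage",
    "load_image",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_gray",
    "px_area_to_um2",
]

MIN_IMAGE_SIDE = 64

#: ITU-R BT.601 luma weights used for the grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Raised when a file does not decode to an 8-bit RGB image."""


@dataclass
class SmearImage:
    """An RGB field of view of a stained blood smear plus its calibration.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        8-bit RGB pixel grid, row-major, origin at top-left.
    microns_per_pixel : float
        Side length of one pixel in micrometers. Strictly positive.
    source_id : str
        Free-text label identifying the image (file name, scene id, ...).
    """

    pixels: np.ndarray
    microns_per_pixel: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected an (H, W, 3) RGB grid, got shape {px.shape}"
            )
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px, "
                f"got {px.shape[0]}x{px.shape[1]}"
            )
        if px.dtype != np.uint8:
            raise ImageFormatError(f"expected uint8 pixels, got {px.dtype}")
        mpp = float(self.microns_per_pixel)
        if not np.isfinite(mpp) or mpp <= 0:
            raise ValueError(f"microns_per_pixel must be finite and > 0, got {mpp}")
        self.pixels = px
        self.microns_per_pixel = mpp

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class HSVImage:
    """Per-pixel (hue, saturation, value): hue in [0, 360) degrees, S and V in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.hue.shape, self.saturation.shape, self.value.shape}
        if len(shapes) != 1:
            raise ValueError("hue/saturation/value grids must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass
class GrayImage:
    """Scalar intensity grid in [0, 255] (float, not re-quantized)."""

    pixels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path, microns_per_pixel: float, source_id: str | None = None) -> SmearImage:
    """Read an 8-bit RGB PNG/TIFF and attach the stated calibration.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ImageFormatError
        If the file does not decode to a 3-channel 8-bit image.
    ValueError
        If *microns_per_pixel* is not finite and positive.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise ImageFormatError(f"could not decode {path!s} as an image: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # tolerate RGBA, drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path!s} is not a 3-channel RGB image (shape {arr.shape})"
        )
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path!s} is not 8-bit per channel ({arr.dtype})")
    return SmearImage(
        pixels=arr,
        microns_per_pixel=microns_per_pixel,
        source_id=source_id if source_id is not None else str(path),
    )


def rgb_to_hsv(img: SmearImage) -> HSVImage:
    """Standard hexcone RGB -> HSV conversion, hue in degrees."""
    hsv = skcolor.rgb2hsv(img.pixels)
    return HSVImage(
        hue=hsv[:, :, 0] * 360.0,
        saturation=hsv[:, :, 1],
        value=hsv[:, :, 2],
    )


def hsv_to_rgb(hsv: HSVImage) -> np.ndarray:
    """Inverse hexcone mapping back to uint8 RGB (round-trip helper)."""
    stacked = np.dstack([hsv.hue / 360.0, hsv.saturation, hsv.value])
    rgb = skcolor.hsv2rgb(stacked)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def rgb_to_gray(img: SmearImage) -> GrayImage:
    """Luminance conversion with BT.601 weights 0.299 R + 0.587 G + 0.114 B."""
    gray = img.pixels.astype(np.float64) @ GRAY_WEIGHTS
    return GrayImage(pixels=gray)


def px_area_to_um2(area_px: float, microns_per_pixel: float) -> float:
    """Convert a pixel area to square micrometers: area_px * mpp**2."""
    if area_px < 0:
        raise ValueError(f"area_px must be >= 0, got {area_px}")
    return float(area_px) * float(microns_per_pixel) ** 2
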
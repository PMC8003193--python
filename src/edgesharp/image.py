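"""Grayscale raster with a physical scale, the common currency of the pipeline.

All images are 2-D 8-bit grayscale arrays indexed ``[row, col]``; point
coordinates elsewhere in the package are ``(x, y) = (col, row)`` with
sub-pixel positions measured in continuous pixel-center coordinates
(0-based).  The scale is the microscope calibration in micrometres per
pixel (``C_OM`` or ``C_SEM``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["ScaledImage", "read_image", "write_image"]


@dataclass
class ScaledImage:
    """An 8-bit grayscale image plus its spatial calibration.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255], indexed [row, col].
    scale
        Micrometres per pixel; must be positive.
    """

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie within [0, 255]")
            px = px.astype(np.uint8)
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        self.pixels = px
        self.scale = float(self.scale)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


def read_image(path: str | Path, scale: float) -> ScaledImage:
    """Read a PNG/TIFF file as a grayscale :class:`ScaledImage`."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = np.round(arr[..., :3].mean(axis=-1)).astype(np.uint8)
    return ScaledImage(arr.astype(np.uint8), scale)


def write_image(img: ScaledImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (format chosen by suffix)."""
    iio.imwrite(path, img.pixels)
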
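"""Edge points, band centerlines, and Sobel gradient directions.

Two kinds of landmark points drive the method:

* **Sharp-reference edge points** (training): Canny edges of the SEM
  image, each annotated with the local gradient direction theta from the
  Sobel operator and with the sign telling which way along theta points
  *outward*, toward the channel exterior.
* **Blurred-band centerline points** (prediction): the skeleton of the
  thresholded dark wall band in the OM image.  Inside a wide dark band the
  raw gradient vanishes, so theta there is taken from the structure tensor
  of a Gaussian-smoothed copy, which recovers the band-normal orientation
  (mod 180 deg); the outward half is then resolved by comparing mean
  intensity along the two candidate directions.

Gradients use the classic 3x3 Sobel kernels applied as cross-correlation
(no kernel flip); theta is the full-quadrant arctangent
``atan2(G_y, G_x)`` in degrees, with G_y computed by a kernel whose
positive direction is *up* the image, so theta follows the mathematical
convention (counter-clockwise from +x) and a unit step along theta moves
``(dx, dy) = (cos theta, -sin theta)`` in image coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate, gaussian_filter, sobel as ndi_sobel
from skimage.feature import canny, structure_tensor
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .image import ScaledImage

__all__ = [
    "SOBEL_KX",
    "SOBEL_KY",
    "GradientField",
    "EdgePointSet",
    "sobel_gradients",
    "gradient_direction",
    "detect_sem_edges",
    "detect_om_centerline_points",
    "direction_vector",
]

logger = logging.getLogger(__name__)

#: Horizontal-derivative Sobel kernel (cross-correlation convention).
SOBEL_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
#: Vertical-derivative Sobel kernel; positive direction is up the image.
SOBEL_KY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.int64)


def direction_vector(theta_deg: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Unit image-coordinate step (dx, dy) for a gradient angle in degrees."""
    th = np.deg2rad(theta_deg)
    return np.cos(th), -np.sin(th)


@dataclass
class GradientField:
    """Per-pixel Sobel gradients and (optionally) their direction.

    ``theta`` is in degrees in (-180, 180], NaN where both gradients vanish
    (direction undefined; such pixels are excluded from edge sets).
    """

    g_x: np.ndarray
    g_y: np.ndarray
    theta: np.ndarray | None = None


def sobel_gradients(img: ScaledImage | np.ndarray) -> GradientField:
    """Cross-correlate the image with the Sobel kernels.

    Accepts a :class:`ScaledImage` or a bare 2-D array (e.g. a smoothed
    float copy).  Integer inputs keep exact integer arithmetic; borders are
    handled by edge replication.
    """
    px = img.pixels if isinstance(img, ScaledImage) else np.asarray(img)
    if px.ndim != 2 or min(px.shape) < 3:
        raise ValueError(f"image must be at least 3x3, got shape {px.shape}")
    work = px.astype(np.int64) if np.issubdtype(px.dtype, np.integer) else px.astype(np.float64)
    g_x = correlate(work, SOBEL_KX.astype(work.dtype), mode="nearest")
    g_y = correlate(work, SOBEL_KY.astype(work.dtype), mode="nearest")
    return GradientField(g_x=g_x, g_y=g_y)


def gradient_direction(field: GradientField) -> GradientField:
    """Fill ``theta`` with the full-quadrant gradient angle in degrees."""
    theta = np.degrees(np.arctan2(field.g_y, field.g_x))
    theta[theta <= -180.0] = 180.0  # canonical range (-180, 180]
    undefined = (field.g_x == 0) & (field.g_y == 0)
    theta[undefined] = np.nan
    field.theta = theta
    return field


def export_gradient_tiff(field: GradientField, path_gx: str, path_gy: str) -> None:
    """Write the gradient components as float32 TIFFs for inspection."""
    import tifffile

    tifffile.imwrite(path_gx, field.g_x.astype(np.float32))
    tifffile.imwrite(path_gy, field.g_y.astype(np.float32))


@dataclass
class EdgePointSet:
    """Sub-pixel points with a gradient angle and an outward sign each.

    ``outward_sign[i] = +1`` means a step along ``theta[i]`` moves toward
    the channel exterior; ``-1`` means it moves inward.
    """

    points: np.ndarray  # (n, 2) of (x, y)
    theta: np.ndarray  # degrees
    outward_sign: np.ndarray  # +/- 1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.outward_sign = np.asarray(self.outward_sign, dtype=np.int8)
        if len(self.points) < 1:
            raise ValueError("an edge point set needs at least one point")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("every retained point must have a defined theta")
        if not np.all(np.abs(self.outward_sign) == 1):
            raise ValueError("outward_sign entries must be +1 or -1")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def outward_theta(self) -> np.ndarray:
        """Angle (degrees, (-180, 180]) whose +direction points outward."""
        th = np.where(self.outward_sign > 0, self.theta, self.theta + 180.0)
        th = np.mod(th + 180.0, 360.0) - 180.0
        th[th <= -180.0] = 180.0
        return th

    def export(self, path: str) -> None:
        """Plain-text table: x, y, theta_deg, sign."""
        rows = np.column_stack([self.points, self.theta, self.outward_sign])
        np.savetxt(path, rows, fmt="%.4f", header="x y theta_deg sign")


def _bilinear(pixels: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    return map_coordinates(pixels.astype(np.float64), [ys, xs], order=1,
                           mode="nearest")


def _outward_signs(
    pixels: np.ndarray,
    pts: np.ndarray,
    theta: np.ndarray,
    reach: int,
) -> np.ndarray:
    """+1 where the +theta side is brighter on average over `reach` samples.

    The channel exterior is bright in this chip design (dark walls/lumen),
    so the brighter side is outward; flip `reach`'s interpretation via the
    caller if a chip with inverted polarity is ever used.
    """
    dx, dy = direction_vector(theta)
    steps = np.arange(1, reach + 1)
    xs = pts[:, 0, None] + steps * dx[:, None]
    ys = pts[:, 1, None] + steps * dy[:, None]
    plus = _bilinear(pixels, xs.ravel(), ys.ravel()).reshape(xs.shape).mean(axis=1)
    xs = pts[:, 0, None] - steps * dx[:, None]
    ys = pts[:, 1, None] - steps * dy[:, None]
    minus = _bilinear(pixels, xs.ravel(), ys.ravel()).reshape(xs.shape).mean(axis=1)
    return np.where(plus >= minus, 1, -1).astype(np.int8)


def detect_sem_edges(
    sem: ScaledImage,
    sigma: float = 1.0,
    low_frac: float = 0.1,
    high_frac: float = 0.3,
    sign_reach: int = 5,
) -> EdgePointSet:
    """Canny edge points of the sharp reference image, with theta and sign.

    Hysteresis thresholds are `low_frac`/`high_frac` of the maximum
    gradient magnitude of the sigma-smoothed image; theta comes from the
    Sobel gradient of the same smoothed copy, and the outward sign from
    the mean intensity over the next `sign_reach` samples along +/-theta.
    """
    px = sem.as_float()
    smoothed = gaussian_filter(px, sigma, mode="nearest")
    gmag = np.hypot(ndi_sobel(smoothed, axis=0), ndi_sobel(smoothed, axis=1))
    gmax = gmag.max()
    if gmax == 0:
        raise ValueError("no edges: image has zero gradient everywhere")
    edge_mask = canny(px, sigma=sigma, low_threshold=low_frac * gmax,
                      high_threshold=high_frac * gmax, use_quantiles=False)
    if not edge_mask.any():
        raise ValueError("no edges detected")
    field = gradient_direction(sobel_gradients(smoothed))
    rows, cols = np.nonzero(edge_mask)
    theta = field.theta[rows, cols]
    keep = np.isfinite(theta)
    if not keep.any():
        raise ValueError("no edge point has a defined gradient direction")
    pts = np.column_stack([cols[keep], rows[keep]]).astype(np.float64)
    theta = theta[keep]
    sign = _outward_signs(px, pts, theta, sign_reach)
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("dropped %d edge pixels with undefined theta", dropped)
    return EdgePointSet(points=pts, theta=theta, outward_sign=sign)


def detect_om_centerline_points(
    om: ScaledImage,
    smooth_sigma: float = 2.0,
    sign_reach: int = 40,
) -> EdgePointSet:
    """Skeleton points of the dark OM wall band, with band-normal theta.

    The band mask is the Otsu-dark region; its skeleton approximates the
    band centerline.  At the band core the intensity gradient is near zero,
    so the normal orientation is estimated from the structure tensor of a
    `smooth_sigma`-smoothed copy (stable mod 180 deg); the outward half is
    the direction whose mean intensity over the next `sign_reach` samples
    is higher — looking inward, the profile eventually crosses the lumen
    and hits the opposite dark band, so the inward mean is lower.
    """
    px = om.as_float()
    dark = om.pixels <= threshold_otsu(om.pixels)
    if not dark.any():
        raise ValueError("no dark band after thresholding")
    skel = skeletonize(dark)
    if not skel.any():
        raise ValueError("empty band skeleton")

    # Structure tensor of the smoothed image: dominant gradient orientation.
    arr, arc, acc = structure_tensor(px, sigma=smooth_sigma, mode="nearest",
                                     order="rc")
    # Principal eigenvector angle from the row axis, in (row, col) axes:
    # phi = 0.5 * atan2(2*Arc, Arr - Acc), so the dominant gradient is
    # (drow, dcol) = (cos phi, sin phi).  In the package convention
    # (g_x, g_y) = (dcol, -drow), giving theta = phi - 90 deg (mod 180).
    phi = 0.5 * np.degrees(np.arctan2(2.0 * arc, arr - acc))
    theta_map = phi - 90.0

    rows, cols = np.nonzero(skel)
    pts = np.column_stack([cols, rows]).astype(np.float64)
    theta = theta_map[rows, cols]
    theta = np.mod(theta + 180.0, 360.0) - 180.0
    theta[theta <= -180.0] = 180.0
    tensor_energy = (arr + acc)[rows, cols]
    keep = np.isfinite(theta) & (tensor_energy > 0)
    if not keep.any():
        raise ValueError("no skeleton point has a defined band normal")
    pts, theta = pts[keep], theta[keep]
    sign = _outward_signs(px, pts, theta, sign_reach)
    return EdgePointSet(points=pts, theta=theta, outward_sign=sign)
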
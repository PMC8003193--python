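"""Synthetic paired sharp/blurred microchannel scenes with known truth edges.

Real training data for this method is a pair of micrographs of the same
microfluidic channel: a sharp SEM image, and an optical-microscope (OM)
image in which each channel wall appears as a thick dark band that is
blurred and systematically displaced toward the channel center relative to
the true structural edge.  This module renders such pairs from an explicit
zigzag-channel geometry so the exact edge coordinates are known, which
makes every downstream stage (edge detection, profile regression,
enhancement, error scoring) testable without microscope data.

Geometry: the channel lumen is the set of points within ``channel_width/2``
of a zigzag centerline polyline that runs horizontally across the image and
turns by ``turning_angle`` degrees at each vertex.  The SEM rendering is a
two-level raster (dark lumen, bright background) with one-pixel
anti-aliasing, so the truth edges — the offset curves at ``channel_width/2``
from the centerline — are meaningful at sub-pixel precision.  The OM
rendering draws each wall as a dark band of ``wall_band_width`` pixels whose
own centerline sits ``edge_offset`` pixels *inside* the true edge (toward
the lumen center), then applies a Gaussian point-spread of ``blur_sigma``
and additive Gaussian noise.  The inward lean of the band reproduces the
asymmetry observed on real chips, where the actual edges lean toward the
channel center relative to the dark OM wall line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .image import ScaledImage, write_image

__all__ = ["SceneSpec", "ScenePair", "render_scene", "render_batch", "write_scene"]

logger = logging.getLogger(__name__)

#: Default spatial calibration, matching a desktop SEM at low magnification.
DEFAULT_SCALE = 0.328  # um / pixel

#: Spacing (pixels of arc length) between consecutive truth-edge samples.
TRUTH_EDGE_SPACING = 0.5


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic OM/SEM scene pair.

    The defaults mimic the imaging regime of a PDMS micromixer chip:
    wall bands about 15 px thick, band-to-edge offsets of 10-15 px, and a
    shared calibration of 0.328 um/pixel after OM-to-SEM rescaling.
    """

    image_height: int = 320
    image_width: int = 320
    turning_angle: float = 30.0  # degrees turned at each zigzag vertex
    channel_width: float = 68.0  # lumen width, px
    wall_band_width: float = 15.0  # thickness of the dark OM wall band, px
    edge_offset: float = 12.0  # band-center displacement toward lumen center, px
    blur_sigma: float = 3.0  # OM point-spread width, px
    noise_sd: float = 3.0  # additive noise, 8-bit intensity units
    background_level: float = 200.0
    wall_level: float = 40.0
    scale: float = DEFAULT_SCALE  # um / pixel
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if not 0 < self.turning_angle < 180:
            raise ValueError("turning_angle must lie in (0, 180) degrees")
        if self.channel_width <= 0 or self.wall_band_width <= 0:
            raise ValueError("channel_width and wall_band_width must be positive")
        if self.edge_offset < 0:
            raise ValueError("edge_offset must be non-negative")
        if not self.blur_sigma > 0:
            raise ValueError("blur_sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.wall_level < self.background_level:
            raise ValueError("walls must be darker than background")
        for level in (self.wall_level, self.background_level):
            if not 0 <= level <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class ScenePair:
    """A rendered scene: sharp reference, blurred counterpart, truth edges."""

    sem_image: ScaledImage
    om_image: ScaledImage
    truth_edges: np.ndarray  # (n, 2) sub-pixel (x, y)
    spec: SceneSpec = field(repr=False)

    def __post_init__(self) -> None:
        if self.sem_image.shape != self.om_image.shape:
            raise ValueError("paired images must share dimensions")
        self.truth_edges = np.asarray(self.truth_edges, dtype=np.float64)


def _zigzag_vertices(spec: SceneSpec) -> np.ndarray:
    """Centerline vertices of the zigzag, extended beyond the image sides.

    Segments alternate headings of +/- turning_angle/2 about horizontal, so
    the direction change at every vertex equals the turning angle.
    """
    h, w = spec.image_height, spec.image_width
    half = np.deg2rad(spec.turning_angle / 2.0)
    run = w / 4.0  # horizontal extent of one zigzag segment
    amp = run * np.tan(half) / 2.0
    cy = (h - 1) / 2.0

    margin = spec.channel_width / 2.0 + 3.0 * spec.blur_sigma + 2.0
    if cy - (amp + margin) < 0 or cy + amp + margin > h - 1:
        raise ValueError(
            "channel geometry exceeds image bounds: zigzag amplitude "
            f"{amp:.1f}px plus wall margin {margin:.1f}px does not fit a "
            f"{h}x{w} image; enlarge the image or reduce turning_angle / "
            "channel_width"
        )

    ext = run  # extend past both sides so buffer end caps fall off-image
    n_seg = int(np.ceil((w - 1 + 2 * ext) / run))
    xs = (w - 1) / 2.0 + (np.arange(n_seg + 1) - n_seg / 2.0) * run
    ys = cy + amp * np.where(np.arange(xs.size) % 2 == 0, 1.0, -1.0)
    return np.column_stack([xs, ys])


def _distance_to_polyline(spec: SceneSpec, verts: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the centerline polyline."""
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.full((h, w), np.inf)
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        dx, dy = x1 - x0, y1 - y0
        seg_len2 = dx * dx + dy * dy
        t = ((xx - x0) * dx + (yy - y0) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d_seg = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        np.minimum(d, d_seg, out=d)
    return d


def _truth_edges(spec: SceneSpec, verts: np.ndarray) -> np.ndarray:
    """Sample the lumen boundary (offset curve at channel_width/2)."""
    ring = LineString(verts).buffer(spec.channel_width / 2.0).exterior
    s = np.arange(0.0, ring.length, TRUTH_EDGE_SPACING)
    pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, s))
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= spec.image_width - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= spec.image_height - 1)
    )
    return pts[inside]


def render_scene(spec: SceneSpec) -> ScenePair:
    """Render one paired scene deterministically from its spec.

    Returns a :class:`ScenePair` whose ``truth_edges`` are the exact
    sub-pixel coordinates of the lumen boundary used to draw the sharp
    image.  Identical specs (including seed) yield bit-identical pixels.
    """
    spec.validate()
    verts = _zigzag_vertices(spec)
    d = _distance_to_polyline(spec, verts)

    # Sharp two-level rendering: dark lumen, bright exterior, 1-px coverage
    # ramp across the boundary so the edge location is sub-pixel meaningful.
    signed = d - spec.channel_width / 2.0  # <0 inside the lumen
    outside_cov = np.clip(signed + 0.5, 0.0, 1.0)
    sem = spec.wall_level + (spec.background_level - spec.wall_level) * outside_cov

    # OM rendering: dark band centered edge_offset px inside the true edge,
    # anti-aliased, then blurred and corrupted by additive noise.
    band_center = spec.channel_width / 2.0 - spec.edge_offset
    band_cov = np.clip(spec.wall_band_width / 2.0 + 0.5 - np.abs(d - band_center), 0.0, 1.0)
    om = spec.background_level - (spec.background_level - spec.wall_level) * band_cov
    om = gaussian_filter(om, spec.blur_sigma, mode="nearest")
    rng = np.random.default_rng(spec.seed)
    om = om + rng.normal(0.0, spec.noise_sd, om.shape)

    sem8 = np.clip(np.round(sem), 0, 255).astype(np.uint8)
    om8 = np.clip(np.round(om), 0, 255).astype(np.uint8)
    return ScenePair(
        sem_image=ScaledImage(sem8, spec.scale),
        om_image=ScaledImage(om8, spec.scale),
        truth_edges=_truth_edges(spec, verts),
        spec=spec,
    )


def render_batch(specs: list[SceneSpec]) -> list[ScenePair]:
    """Render a list of scenes; failures carry the offending scene index."""
    pairs = []
    for i, spec in enumerate(specs):
        try:
            pairs.append(render_scene(spec))
        except ValueError as exc:
            raise ValueError(f"scene {i}: {exc}") from exc
    return pairs


def write_scene(pair: ScenePair, out_dir: str | Path, stem: str = "scene") -> None:
    """Write a rendered pair as PNGs plus plain-text truth and JSON spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(pair.sem_image, out / f"{stem}_sem.png")
    write_image(pair.om_image, out / f"{stem}_om.png")
    np.savetxt(out / f"{stem}_truth_edges.txt", pair.truth_edges,
               fmt="%.3f", header="x y")
    (out / f"{stem}_spec.json").write_text(json.dumps(asdict(pair.spec), indent=2))
    logger.info("wrote scene '%s' to %s", stem, out)
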
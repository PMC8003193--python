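"""Intensity-profile extraction, target assignment, and dataset assembly.

The regression features are 1-D intensity profiles of length ``L`` pixels
sampled from the blurred OM image along the outward edge normal.  A profile
whose sampling segment spans ``-t*L .. (1-t)*L`` around the generating edge
point (negative = channel interior) carries the normalized target ``t``:
the true edge sits at fraction ``t`` of the profile, e.g. a symmetric
``-0.5L..0.5L`` extraction has target 0.5 and a ``-0.1L..0.9L`` extraction
has target 0.1.  Each reference edge point is sampled several times with
the split fraction drawn at random, which augments the training set and
teaches the network to locate the edge anywhere within the window.

Datasets are split 70/25/5 into train/validation/test by a seeded
permutation, and features are min-max normalized per row to [0, 1] (stored
invertibly) so they sit in the sigmoid-friendly range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .edges import EdgePointSet, direction_vector
from .image import ScaledImage

__all__ = [
    "ProfileConfig",
    "IntensityProfile",
    "ProfileDataset",
    "ProfileOutOfBounds",
    "sample_profile",
    "build_training_set",
    "build_prediction_set",
]

logger = logging.getLogger(__name__)

SPLIT_FRACTIONS = {"train": 0.70, "val": 0.25, "test": 0.05}


class ProfileOutOfBounds(ValueError):
    """A sampling segment leaves the image."""


@dataclass(frozen=True)
class ProfileConfig:
    """Extraction settings.

    ``offset_range`` bounds the random split fraction; the default
    [0.1, 0.9] keeps the edge away from the extreme profile ends, where
    there is no context left to regress on.  ``fixed_grid=True`` replaces
    the random draws with `samples_per_point` evenly spaced fractions.
    ``point_stride`` subsamples the edge points (every k-th), which scales
    the dataset down without changing the sampling geometry.
    """

    length: int = 100  # L, pixels
    samples_per_point: int = 9
    offset_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0
    fixed_grid: bool = False
    point_stride: int = 1

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("profile length must be at least 2")
        if self.samples_per_point < 1:
            raise ValueError("samples_per_point must be at least 1")
        lo, hi = self.offset_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("offset_range must satisfy 0 <= lo <= hi <= 1")
        if self.point_stride < 1:
            raise ValueError("point_stride must be at least 1")


@dataclass
class IntensityProfile:
    """One sampled profile: raw values, target fraction, and its origin."""

    values: np.ndarray  # (L,)
    target_t: float  # position of the true edge within the profile, [0, 1]
    origin: tuple[float, float, float]  # (x, y, outward theta in degrees)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not 0.0 <= self.target_t <= 1.0:
            raise ValueError("target must lie in [0, 1]")


def _segment_coords(
    x: float | np.ndarray,
    y: float | np.ndarray,
    theta: float | np.ndarray,
    start_frac: float | np.ndarray,
    length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates at unit spacing along the outward direction.

    Sample i sits at signed distance ``i - start_frac*L`` from the origin
    (negative = interior), so the origin point itself is at profile
    fraction ``start_frac``.
    """
    idx = np.arange(length, dtype=np.float64)
    offs = idx - np.asarray(start_frac)[..., None] * length
    dx, dy = direction_vector(np.asarray(theta))
    xs = np.asarray(x)[..., None] + offs * np.asarray(dx)[..., None]
    ys = np.asarray(y)[..., None] + offs * np.asarray(dy)[..., None]
    return xs, ys


def sample_profile(
    img: ScaledImage,
    point: tuple[float, float],
    theta: float,
    start_frac: float,
    length: int,
) -> IntensityProfile:
    """Sample one length-L profile along the outward direction `theta`.

    The segment spans ``-start_frac*L`` (interior) to ``(1-start_frac)*L``
    (exterior) around `point` at unit-pixel spacing with bilinear
    interpolation; the assigned target equals `start_frac`.  Raises
    :class:`ProfileOutOfBounds` if any sample falls outside the image.
    """
    if not 0.0 <= start_frac <= 1.0:
        raise ValueError("start_frac must lie in [0, 1]")
    x, y = point
    xs, ys = _segment_coords(x, y, theta, start_frac, length)
    h, w = img.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ProfileOutOfBounds(
            f"profile at ({x:.1f}, {y:.1f}) theta={theta:.1f} exits the image"
        )
    values = map_coordinates(img.as_float(), [ys.ravel(), xs.ravel()],
                             order=1, mode="nearest")
    return IntensityProfile(values=values, target_t=float(start_frac),
                            origin=(float(x), float(y), float(theta)))


@dataclass
class ProfileDataset:
    """Feature matrix with targets, split labels, and inversion parameters.

    ``features`` are per-row min-max normalized to [0, 1]; the raw profile
    is ``features * norm_range[:, None] + norm_min[:, None]``.  For
    prediction sets the targets are NaN and every row's ``start_frac`` is
    the centered 0.5.
    """

    features: np.ndarray  # (n, L), normalized
    targets: np.ndarray  # (n,), NaN for prediction sets
    start_frac: np.ndarray  # (n,)
    split: np.ndarray  # (n,) of 'train' / 'val' / 'test' / 'predict'
    origins: np.ndarray  # (n, 3) of (x, y, outward theta)
    norm_min: np.ndarray = field(repr=False, default=None)
    norm_range: np.ndarray = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.features)

    def rows(self, split_name: str) -> np.ndarray:
        return np.nonzero(self.split == split_name)[0]

    def to_csv(self, path: str) -> None:
        """One row = L features + target + split label."""
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow([f"f{i}" for i in range(self.length)] + ["target", "split"])
            for f, t, s in zip(self.features, self.targets, self.split):
                wr.writerow(list(np.round(f, 6)) + [t, s])


def _normalize_rows(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mn = raw.min(axis=1)
    rng = raw.max(axis=1) - mn
    flat = rng < 1e-9
    safe = np.where(flat, 1.0, rng)
    feats = (raw - mn[:, None]) / safe[:, None]
    feats[flat] = 0.0
    return feats, mn, np.where(flat, 1.0, rng)


def _assign_splits(n: int, rng: np.random.Generator) -> np.ndarray:
    n_train = int(round(SPLIT_FRACTIONS["train"] * n))
    n_val = int(round(SPLIT_FRACTIONS["val"] * n))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    labels = np.array(["train"] * n_train + ["val"] * n_val
                      + ["test"] * (n - n_train - n_val))
    return labels[rng.permutation(n)]


def build_training_set(
    om: ScaledImage,
    sem_edges: EdgePointSet,
    cfg: ProfileConfig,
) -> ProfileDataset:
    """Augmented training profiles at reference edge points.

    Each retained edge point contributes exactly ``samples_per_point``
    profiles sampled from the *blurred* image with split fractions drawn
    uniformly (seeded) from ``offset_range`` (or a fixed grid); a point is
    dropped whole if any of its segments would leave the image, so the row
    count is retained points x samples_per_point.  Rows are split 70/25/5
    by a seeded permutation.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    lo, hi = cfg.offset_range
    pts = sem_edges.points[::cfg.point_stride]
    thetas = sem_edges.outward_theta[::cfg.point_stride]
    h, w = om.shape
    img = om.as_float()

    feats, targs, origins = [], [], []
    kept = dropped = 0
    for (x, y), th in zip(pts, thetas):
        if cfg.fixed_grid:
            fracs = np.linspace(lo, hi, cfg.samples_per_point)
        else:
            fracs = rng.uniform(lo, hi, cfg.samples_per_point)
        xs, ys = _segment_coords(x, y, th, fracs, L)
        if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
            dropped += 1
            continue
        vals = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                               mode="nearest").reshape(cfg.samples_per_point, L)
        feats.append(vals)
        targs.append(fracs)
        origins.append(np.broadcast_to([x, y, th], (cfg.samples_per_point, 3)))
        kept += 1
    if dropped:
        logger.info("dropped %d/%d edge points whose profiles leave the image",
                    dropped, kept + dropped)
    if kept < 10:
        raise ValueError(f"only {kept} usable edge points (need at least 10)")

    raw = np.vstack(feats)
    features, mn, rngs = _normalize_rows(raw)
    targets = np.concatenate(targs)
    return ProfileDataset(
        features=features,
        targets=targets,
        start_frac=targets.copy(),
        split=_assign_splits(len(targets), rng),
        origins=np.vstack(origins),
        norm_min=mn,
        norm_range=rngs,
    )


def build_prediction_set(
    om: ScaledImage,
    om_centerline: EdgePointSet,
    cfg: ProfileConfig,
) -> ProfileDataset:
    """Centered profiles (start fraction 0.5) at band-centerline points.

    One profile per point; points whose segment leaves the image are
    skipped individually (count logged).  Targets are NaN — the network
    supplies them — and origins are retained so predictions can be mapped
    back to image coordinates.
    """
    L = cfg.length
    pts = om_centerline.points
    thetas = om_centerline.outward_theta
    h, w = om.shape
    img = om.as_float()

    xs, ys = _segment_coords(pts[:, 0], pts[:, 1], thetas,
                             np.full(len(pts), 0.5), L)
    ok = ((xs.min(axis=1) >= 0) & (xs.max(axis=1) <= w - 1)
          & (ys.min(axis=1) >= 0) & (ys.max(axis=1) <= h - 1))
    skipped = int((~ok).sum())
    if skipped:
        logger.info("skipped %d/%d centerline points near the border",
                    skipped, len(pts))
    if not ok.any():
        raise ValueError("no centerline profile fits inside the image")
    raw = map_coordinates(img, [ys[ok].ravel(), xs[ok].ravel()], order=1,
                          mode="nearest").reshape(-1, L)
    features, mn, rngs = _normalize_rows(raw)
    n = len(raw)
    return ProfileDataset(
        features=features,
        targets=np.full(n, np.nan),
        start_frac=np.full(n, 0.5),
        split=np.array(["predict"] * n),
        origins=np.column_stack([pts[ok], thetas[ok]]),
        norm_min=mn,
        norm_range=rngs,
    )
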
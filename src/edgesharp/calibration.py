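"""Scale calibration and rigid OM/SEM registration by channel centerlines.

The two micrographs come from different instruments, so before any
learning the OM image is resampled to the SEM pixel pitch using the
calibration ratio ``C_cali = C_OM / C_SEM`` (both in um/pixel), and the
pair is registered rigidly.  The registration reference is the midline of
the channel lumen in each image: the alignment score for a candidate
(dx, dy, rotation) is the summed distance from each transformed moving
centerline point to its nearest reference centerline point, and the best
alignment is the transform with the lowest score.  The search is an
exhaustive coarse grid followed by Nelder-Mead local refinement; every
evaluated transform is recorded in the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, distance_transform_edt
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .image import ScaledImage

__all__ = [
    "Centerline",
    "AlignmentResult",
    "GridSearch",
    "calibration_factor",
    "rescale_to_reference",
    "extract_centerline",
    "align_by_centerlines",
    "apply_alignment",
]

logger = logging.getLogger(__name__)

_MIN_CENTERLINE_PX = 20  # shortest skeleton path accepted as a centerline


def calibration_factor(c_om: float, c_sem: float) -> float:
    """Calibration ratio ``C_cali = C_OM / C_SEM`` between the two scales.

    Both arguments are microscope calibrations in um/pixel and must be
    positive.  Resampling the OM image by this ratio brings it to the SEM
    pixel pitch.
    """
    if not (c_om > 0 and c_sem > 0):
        raise ValueError(f"scales must be positive, got ({c_om}, {c_sem})")
    return c_om / c_sem


def rescale_to_reference(om: ScaledImage, sem: ScaledImage) -> ScaledImage:
    """Resample the OM image to the SEM scale with nearest-neighbor lookup.

    The output has ``round(size * C_cali)`` pixels per axis and carries the
    SEM scale; every output pixel is a copy of one source pixel.
    """
    f = calibration_factor(om.scale, sem.scale)
    h, w = om.shape
    nh, nw = int(round(h * f)), int(round(w * f))
    if nh < 2 or nw < 2:
        raise ValueError(f"rescaled size {nh}x{nw} is degenerate (< 2x2)")
    rows = np.minimum(np.floor((np.arange(nh) + 0.5) / f).astype(int), h - 1)
    cols = np.minimum(np.floor((np.arange(nw) + 0.5) / f).astype(int), w - 1)
    return ScaledImage(om.pixels[np.ix_(rows, cols)], sem.scale)


@dataclass
class Centerline:
    """Ordered sub-pixel path of a channel lumen midline."""

    points: np.ndarray  # (n, 2) of (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("a centerline needs at least two (x, y) points")
        steps = np.hypot(*np.diff(pts, axis=0).T)
        if steps.max() > 3.0:
            raise ValueError("centerline has a gap larger than 3 px between "
                             "consecutive points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def _ordered_skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Skeletonize a mask and order the longest skeleton path end to end.

    Works on the largest 8-connected skeleton component; the path is the
    longest shortest-path between skeleton endpoints (double BFS, valid for
    the near-tree graphs skeletonization produces).
    """
    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("skeletonization produced no foreground")
    lab = label(skel, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    rows, cols = np.nonzero(lab == largest)
    coords = list(zip(rows.tolist(), cols.tolist()))
    index = {rc: i for i, rc in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, list[int]]:
        parent = {start: -1}
        frontier, last = [start], start
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        path, u = [], last
        while u != -1:
            path.append(u)
            u = parent[u]
        return last, path[::-1]

    far, _ = bfs(0)
    _, path = bfs(far)
    return np.array([(coords[i][1], coords[i][0]) for i in path], dtype=np.float64)


def _lumen_mask(img: ScaledImage, polarity: str) -> np.ndarray:
    """Binary mask of the channel lumen for either image modality."""
    px = img.pixels
    thr = threshold_otsu(px)
    dark = px <= thr  # inclusive: Otsu returns the lower level on 2-level images
    if polarity == "two-level":
        # Sharp reference: the lumen is simply the dark region.
        mask = dark
    elif polarity == "dark-band":
        # Blurred modality: the walls are dark bands; the lumen is the
        # narrow bright corridor squeezed between them, i.e. the bright
        # component whose pixels stay closest to dark pixels on average
        # (open background regions stretch far from any wall).
        bright = ~dark
        dist_to_dark = distance_transform_edt(bright)
        lab = label(bright, connectivity=1)
        best, best_score = 0, np.inf
        for comp in range(1, lab.max() + 1):
            m = lab == comp
            if m.sum() < _MIN_CENTERLINE_PX:
                continue
            score = dist_to_dark[m].mean()
            if score < best_score:
                best, best_score = comp, score
        if best == 0:
            raise ValueError("no candidate lumen region between dark bands")
        mask = lab == best
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not mask.any():
        raise ValueError("no foreground after thresholding")
    return mask


def extract_centerline(img: ScaledImage, polarity: str = "two-level") -> Centerline:
    """Extract the ordered lumen midline of a channel image.

    ``polarity='two-level'`` treats dark pixels as the lumen (sharp
    reference images); ``polarity='dark-band'`` finds the bright lumen
    enclosed between dark wall bands (blurred images).  Otsu thresholding,
    morphological skeletonization and path ordering; rejects images whose
    skeleton path is shorter than 20 px.
    """
    path = _ordered_skeleton_path(_lumen_mask(img, polarity))
    if len(path) < _MIN_CENTERLINE_PX:
        raise ValueError(f"skeleton path of {len(path)} px is too short")
    return Centerline(path)


@dataclass(frozen=True)
class GridSearch:
    """Coarse search grid for the rigid alignment."""

    max_shift: float = 10.0  # px, both axes
    shift_step: float = 2.0
    max_rotation: float = 5.0  # degrees
    rotation_step: float = 1.0
    refine: bool = True

    def shifts(self) -> np.ndarray:
        return np.arange(-self.max_shift, self.max_shift + 1e-9, self.shift_step)

    def rotations(self) -> np.ndarray:
        return np.arange(-self.max_rotation, self.max_rotation + 1e-9,
                         self.rotation_step)


@dataclass
class AlignmentResult:
    """Best rigid transform and the full search history."""

    translation: tuple[float, float]  # (dx, dy) px
    rotation: float  # degrees, about `pivot`
    score: float  # summed nearest-point distance at the optimum
    pivot: tuple[float, float]
    trace: list[tuple[float, float, float, float]] = field(repr=False)
    # trace rows: (dx, dy, rotation_deg, score)


def _transform_points(pts: np.ndarray, dx: float, dy: float, rot_deg: float,
                      pivot: tuple[float, float]) -> np.ndarray:
    th = np.deg2rad(rot_deg)
    rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (pts - pivot) @ rotm.T + pivot + (dx, dy)


def align_by_centerlines(
    ref: Centerline,
    moving: Centerline,
    search: GridSearch | None = None,
    pivot: tuple[float, float] | None = None,
    symmetric: bool = False,
) -> AlignmentResult:
    """Find the rigid transform of `moving` minimizing summed point distance.

    The score is the directed sum over moving points of the distance to the
    nearest reference point (``symmetric=True`` adds the reverse direction).
    An exhaustive coarse grid over (dx, dy, rotation) is followed by
    Nelder-Mead refinement from the grid optimum; every evaluation is
    appended to the trace and the returned transform attains the minimal
    traced score.  Rotation is about `pivot` (default: moving-point
    centroid, standing in for the image center when aligning full frames).
    """
    search = search or GridSearch()
    ref_pts = ref.points if isinstance(ref, Centerline) else \
        np.atleast_2d(np.asarray(ref, dtype=np.float64))
    mov_pts = moving.points if isinstance(moving, Centerline) else \
        np.atleast_2d(np.asarray(moving, dtype=np.float64))
    if len(ref_pts) == 0 or len(mov_pts) == 0:
        raise ValueError("centerlines must be non-empty")
    if pivot is None:
        pivot = tuple(mov_pts.mean(axis=0))
    ref_tree = cKDTree(ref_pts)
    mov_tree = cKDTree(mov_pts) if symmetric else None

    trace: list[tuple[float, float, float, float]] = []

    def score_at(dx: float, dy: float, rot: float) -> float:
        pts = _transform_points(mov_pts, dx, dy, rot, pivot)
        s = ref_tree.query(pts)[0].sum()
        if symmetric:
            back = _transform_points(ref_pts, -dx, -dy, -rot, pivot)  # approx inverse
            s += mov_tree.query(back)[0].sum()
        trace.append((dx, dy, rot, s))
        return s

    shifts, rots = search.shifts(), search.rotations()
    if shifts.size == 0 or rots.size == 0:
        raise ValueError("empty search grid")
    for rot in rots:  # rotation outermost: the trace oscillates with angle
        for dx in shifts:
            for dy in shifts:
                score_at(dx, dy, rot)

    best_i = int(np.argmin([t[3] for t in trace]))
    bdx, bdy, brot, _ = trace[best_i]

    if search.refine:
        minimize(
            lambda p: score_at(p[0], p[1], p[2]),
            x0=[bdx, bdy, brot],
            method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-6, "maxiter": 200},
        )
    best_i = int(np.argmin([t[3] for t in trace]))  # earliest minimum wins ties
    bdx, bdy, brot, bscore = trace[best_i]
    return AlignmentResult(
        translation=(bdx, bdy),
        rotation=brot,
        score=bscore,
        pivot=pivot,
        trace=trace,
    )


def apply_alignment(
    img: ScaledImage,
    result: AlignmentResult,
    fill: float | None = None,
) -> ScaledImage:
    """Resample an image under the recovered rigid transform.

    Forward model: a point p of `img` maps to ``R(p - pivot) + pivot + t``.
    The output pixel at o therefore samples ``R^-1(o - t - pivot) + pivot``
    with nearest-neighbor lookup (consistent with the nearest rescaling).
    Out-of-bounds pixels take `fill` (default: median border intensity).
    """
    if fill is None:
        px = img.pixels
        border = np.concatenate([px[0], px[-1], px[:, 0], px[:, -1]])
        fill = float(np.median(border))
    th = np.deg2rad(result.rotation)
    # In (row, col) coordinates: (x, y) = (col, row).
    rot_rc = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    inv = rot_rc.T
    pivot_rc = np.array([result.pivot[1], result.pivot[0]])
    t_rc = np.array([result.translation[1], result.translation[0]])
    offset = pivot_rc - inv @ (t_rc + pivot_rc)
    out = affine_transform(
        img.pixels, inv, offset=offset, order=0, mode="constant", cval=fill,
        output=np.uint8,
    )
    return ScaledImage(out, img.scale)


def export_trace(result: AlignmentResult, path: str) -> None:
    """Write the alignment search history as CSV (iter, dx, dy, rot, score)."""
    rows = np.array([(i, *t) for i, t in enumerate(result.trace)])
    np.savetxt(path, rows, delimiter=",", fmt="%.6g",
               header="iteration,dx,dy,rotation_deg,score", comments="")
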
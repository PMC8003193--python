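"""Prediction scoring, the end-to-end scene pipeline, and the L sweep.

Prediction error is the Euclidean distance from each predicted edge point
to the nearest reference (truth) point — exact nearest-neighbor, computed
with a spatial index but identical to brute force.  Summaries report the
mean, median and quartiles in pixels and micrometres, and flag outliers by
the boxplot rule: distance greater than Q3 + 1.5 IQR.

The feature-length sweep re-runs the whole extract / train / predict /
evaluate pipeline for a range of profile lengths L on the same scenes,
which probes the method's central geometric constraint: the profile window
must reach the true edge, which lies 10-15 px outside the band centerline
where prediction profiles are centered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .edges import EdgePointSet, detect_om_centerline_points, detect_sem_edges
from .network import (PredictedPositions, ShallowNet, TrainReport,
                      TrainConfig, predict_positions, train_lm)
from .profiles import ProfileConfig, ProfileDataset, build_prediction_set, \
    build_training_set
from .scene import ScenePair

__all__ = [
    "ErrorReport",
    "SweepResult",
    "SceneRun",
    "nearest_point_errors",
    "correlation_report",
    "process_scene",
    "length_sweep",
    "convergence_length",
]

logger = logging.getLogger(__name__)


@dataclass
class ErrorReport:
    """Nearest-point distances and their summary statistics."""

    distances_px: np.ndarray
    distances_um: np.ndarray
    mean_px: float
    mean_um: float
    median_px: float
    q1_px: float
    q3_px: float
    outlier_threshold_px: float  # Q3 + 1.5 * IQR
    outlier_mask: np.ndarray = field(repr=False)
    n: int = 0

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())

    def to_json(self, path: str) -> None:
        summary = {
            "n": self.n,
            "mean_px": self.mean_px,
            "mean_um": self.mean_um,
            "median_px": self.median_px,
            "q1_px": self.q1_px,
            "q3_px": self.q3_px,
            "outlier_threshold_px": self.outlier_threshold_px,
            "n_outliers": self.n_outliers,
        }
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)


def nearest_point_errors(
    predicted: np.ndarray,
    reference: np.ndarray,
    scale: float,
) -> ErrorReport:
    """Score predicted points against the nearest reference point each.

    Directed predicted-to-reference distances (no symmetric Hausdorff);
    `scale` converts pixels to micrometres.  Both point lists must be
    non-empty.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=np.float64))
    reference = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    if len(predicted) == 0 or len(reference) == 0:
        raise ValueError("point lists must be non-empty")
    d = cKDTree(reference).query(predicted)[0]
    q1, q3 = np.percentile(d, [25, 75])
    thr = q3 + 1.5 * (q3 - q1)
    return ErrorReport(
        distances_px=d,
        distances_um=d * scale,
        mean_px=float(d.mean()),
        mean_um=float(d.mean() * scale),
        median_px=float(np.median(d)),
        q1_px=float(q1),
        q3_px=float(q3),
        outlier_threshold_px=float(thr),
        outlier_mask=d > thr,
        n=len(d),
    )


def correlation_report(
    predictions: np.ndarray,
    targets: np.ndarray,
    split: np.ndarray,
) -> dict[str, float]:
    """Pearson correlation per split plus overall ('all').

    Zero-variance targets or predictions in a split yield NaN for that
    split (flagged undefined rather than raising).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    split = np.asarray(split)

    def pearson(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    out = {s: pearson(predictions[split == s], targets[split == s])
           for s in dict.fromkeys(split.tolist())}
    out["all"] = pearson(predictions, targets)
    return out


@dataclass
class SceneRun:
    """Everything one pipeline pass over a scene pair produces."""

    sem_edges: EdgePointSet
    om_points: EdgePointSet
    training: ProfileDataset
    net: ShallowNet
    report: TrainReport
    prediction_set: ProfileDataset
    predictions: PredictedPositions
    errors: ErrorReport
    correlations: dict[str, float]
    baseline: ErrorReport  # OM band centerline scored against truth


def process_scene(
    pair: ScenePair,
    profile_cfg: ProfileConfig | None = None,
    train_cfg: TrainConfig | None = None,
    clip: bool = False,
) -> SceneRun:
    """Run detect -> extract -> train -> predict -> score on one pair.

    The pair's images are assumed registered (synthetic pairs are by
    construction; real pairs should pass through the calibration module
    first).  The baseline report scores the raw band-centerline points so
    the improvement from the network is measurable.
    """
    profile_cfg = profile_cfg or ProfileConfig()
    train_cfg = train_cfg or TrainConfig()
    sem_edges = detect_sem_edges(pair.sem_image)
    om_points = detect_om_centerline_points(pair.om_image)
    training = build_training_set(pair.om_image, sem_edges, profile_cfg)
    net, report = train_lm(training, train_cfg)
    pred_set = build_prediction_set(pair.om_image, om_points, profile_cfg)
    preds = predict_positions(net, pred_set, clip=clip)
    scale = pair.om_image.scale
    errors = nearest_point_errors(preds.points_xy, pair.truth_edges, scale)
    baseline = nearest_point_errors(pred_set.origins[:, :2], pair.truth_edges,
                                    scale)
    corrs = correlation_report(
        predict_positions(net, training).fractions, training.targets,
        training.split,
    )
    return SceneRun(
        sem_edges=sem_edges,
        om_points=om_points,
        training=training,
        net=net,
        report=report,
        prediction_set=pred_set,
        predictions=preds,
        errors=errors,
        correlations=corrs,
        baseline=baseline,
    )


@dataclass
class SweepResult:
    """Per-length pooled results of the feature-length sweep."""

    lengths: np.ndarray  # strictly increasing
    mean_error_px: np.ndarray
    mean_error_um: np.ndarray
    epochs: np.ndarray  # mean stop epoch across scenes
    test_correlation: np.ndarray  # mean held-out r across scenes
    failures: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("lengths must be strictly increasing")

    def export_csv(self, path: str) -> None:
        rows = np.column_stack([self.lengths, self.mean_error_px,
                                self.mean_error_um, self.epochs,
                                self.test_correlation])
        np.savetxt(path, rows, delimiter=",", fmt="%.6g",
                   header="L,mean_error_px,mean_error_um,epochs,test_r",
                   comments="")


def length_sweep(
    scenes: list[ScenePair],
    lengths: list[int],
    profile_cfg: ProfileConfig | None = None,
    train_cfg: TrainConfig | None = None,
    clip: bool = False,
) -> SweepResult:
    """Re-run the full pipeline at each profile length L.

    Errors are pooled over all scenes' predicted points at each L.  A
    training failure at some L is recorded and the sweep continues with
    NaN entries for that L.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    lengths = sorted(int(L) for L in lengths)
    base = profile_cfg or ProfileConfig()
    train_cfg = train_cfg or TrainConfig()

    err_px, err_um, eps, rs = [], [], [], []
    failures: list[tuple[int, str]] = []
    for L in lengths:
        cfg = ProfileConfig(
            length=L,
            samples_per_point=base.samples_per_point,
            offset_range=base.offset_range,
            seed=base.seed,
            fixed_grid=base.fixed_grid,
            point_stride=base.point_stride,
        )
        pooled, pooled_um, ep, rr = [], [], [], []
        try:
            for pair in scenes:
                run = process_scene(pair, cfg, train_cfg, clip=clip)
                pooled.append(run.errors.distances_px)
                pooled_um.append(run.errors.distances_um)
                ep.append(run.report.stop_epoch)
                rr.append(run.correlations.get("test", np.nan))
            err_px.append(float(np.concatenate(pooled).mean()))
            err_um.append(float(np.concatenate(pooled_um).mean()))
            eps.append(float(np.mean(ep)))
            rs.append(float(np.nanmean(rr)))
        except (ValueError, FloatingPointError) as exc:
            logger.warning("sweep failed at L=%d: %s", L, exc)
            failures.append((L, str(exc)))
            err_px.append(np.nan)
            err_um.append(np.nan)
            eps.append(np.nan)
            rs.append(np.nan)
    return SweepResult(
        lengths=np.array(lengths),
        mean_error_px=np.array(err_px),
        mean_error_um=np.array(err_um),
        epochs=np.array(eps),
        test_correlation=np.array(rs),
        failures=failures,
    )


def convergence_length(sweep: SweepResult, rel_tol: float = 0.2) -> int:
    """Smallest L whose mean error is within `rel_tol` of the longest L's."""
    ref = sweep.mean_error_px[-1]
    if not np.isfinite(ref):
        raise ValueError("no finite error at the longest length")
    ok = sweep.mean_error_px <= (1.0 + rel_tol) * ref
    return int(sweep.lengths[np.argmax(ok)])
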
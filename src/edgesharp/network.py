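"""Single-hidden-layer regression network trained by Levenberg-Marquardt.

Architecture: ``y = w_O . sigmoid(w_H x + b_H) + b_O`` — a logistic hidden
layer of ``N_H`` neurons (default 20) over the L-pixel profile, and a
linear scalar output that regresses the normalized edge position.

Training is classic full-batch Levenberg-Marquardt on the train split:
with residuals r = y - t and their analytic Jacobian J, each step solves

    (J'J + mu I) dp = -J'r

The damping mu is decreased after an accepted step (training MSE strictly
decreased) and increased after a rejection, so accepted steps never
increase the training error.  One epoch is one accepted pass.  Training
stops when the validation MSE has not decreased for `patience` epochs
(default 6) or at `max_epochs` (default 1000); the returned parameters are
the snapshot from the best-validation epoch, which can precede the stop
epoch.

A raw prediction is the fraction of the profile at which the edge lies;
position = output x L pixels along the sampling segment.  The linear
output is deliberately not clipped to [0, 1] by default: prediction
profiles are centered on the blurred band centerline, which sits 10-15 px
inside the true edge, so for short profiles the network must be able to
extrapolate an edge position just past the window end.  Pass ``clip=True``
to force outputs into [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .edges import direction_vector
from .profiles import ProfileDataset

__all__ = [
    "ShallowNet",
    "TrainConfig",
    "TrainReport",
    "PredictedPositions",
    "init_net",
    "forward",
    "jacobian",
    "train_lm",
    "predict_positions",
    "save_net",
    "load_net",
]

logger = logging.getLogger(__name__)

FILE_FORMAT = "edgesharp-shallow-net"
FILE_VERSION = 1


@dataclass
class ShallowNet:
    """Weights and biases of the two-layer network."""

    w_h: np.ndarray  # (N_H, L) hidden weights
    b_h: np.ndarray  # (N_H,) hidden biases
    w_o: np.ndarray  # (N_H,) output weights
    b_o: float  # output bias
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.w_h = np.atleast_2d(np.asarray(self.w_h, dtype=np.float64))
        self.b_h = np.asarray(self.b_h, dtype=np.float64).ravel()
        self.w_o = np.asarray(self.w_o, dtype=np.float64).ravel()
        self.b_o = float(self.b_o)
        n_h = self.w_h.shape[0]
        if self.b_h.shape != (n_h,) or self.w_o.shape != (n_h,):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.w_h, self.b_h, self.w_o):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.w_h.shape[0]

    @property
    def length(self) -> int:
        return self.w_h.shape[1]

    @property
    def n_params(self) -> int:
        n_h, L = self.w_h.shape
        return n_h * L + n_h + n_h + 1

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w_h.ravel(), self.b_h, self.w_o,
                               [self.b_o]])

    def unpack(self, p: np.ndarray) -> None:
        n_h, L = self.w_h.shape
        k = n_h * L
        self.w_h = p[:k].reshape(n_h, L)
        self.b_h = p[k:k + n_h].copy()
        self.w_o = p[k + n_h:k + 2 * n_h].copy()
        self.b_o = float(p[-1])

    def copy(self) -> "ShallowNet":
        return ShallowNet(self.w_h.copy(), self.b_h.copy(), self.w_o.copy(),
                          self.b_o, dict(self.meta))


def init_net(length: int, n_hidden: int = 20, seed: int = 0) -> ShallowNet:
    """Seeded Nguyen-Widrow-style initialization for inputs in [0, 1].

    Hidden weight rows are drawn uniformly, rescaled to the Nguyen-Widrow
    magnitude ``0.7 * N_H**(1/L)``, and biases spread the active regions of
    the sigmoids across the input range; output weights start small.
    """
    rng = np.random.default_rng(seed)
    w_h = rng.uniform(-1.0, 1.0, (n_hidden, length))
    beta = 0.7 * n_hidden ** (1.0 / length)
    norms = np.linalg.norm(w_h, axis=1, keepdims=True)
    w_h = beta * w_h / np.where(norms == 0, 1.0, norms)
    b_h = beta * np.linspace(-1.0, 1.0, n_hidden) * np.sign(w_h[:, 0] + 1e-12)
    w_o = rng.uniform(-0.5, 0.5, n_hidden) / np.sqrt(n_hidden)
    b_o = rng.uniform(-0.1, 0.1)
    return ShallowNet(w_h, b_h, w_o, b_o, meta={"seed": seed})


def _hidden(net: ShallowNet, features: np.ndarray) -> np.ndarray:
    return expit(features @ net.w_h.T + net.b_h)


def forward(net: ShallowNet, features: np.ndarray) -> np.ndarray:
    """Network outputs for an (n, L) feature matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != net.length:
        raise ValueError(
            f"feature width {features.shape[1]} != network input size {net.length}"
        )
    return _hidden(net, features) @ net.w_o + net.b_o


def jacobian(net: ShallowNet, features: np.ndarray) -> np.ndarray:
    """Analytic (n, P) Jacobian of the outputs w.r.t. all parameters.

    Column order matches :meth:`ShallowNet.pack`: w_h (row-major), b_h,
    w_o, b_o.  Because residuals are ``y - t``, this is also the residual
    Jacobian.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != net.length:
        raise ValueError("feature width does not match network input size")
    n = features.shape[0]
    h = _hidden(net, features)  # (n, N_H)
    hprime = h * (1.0 - h)
    g = hprime * net.w_o  # dy/dz_j per row, (n, N_H)
    J = np.empty((n, net.n_params))
    k = net.n_hidden * net.length
    # dy/dw_h[j, k] = g_j * x_k
    J[:, :k] = (g[:, :, None] * features[:, None, :]).reshape(n, k)
    J[:, k:k + net.n_hidden] = g  # dy/db_h
    J[:, k + net.n_hidden:k + 2 * net.n_hidden] = h  # dy/dw_o
    J[:, -1] = 1.0  # dy/db_o
    return J


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt training settings."""

    max_epochs: int = 1000
    patience: int = 6  # epochs without validation improvement before stopping
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    n_hidden: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if not self.mu_init > 0:
            raise ValueError("mu_init must be positive")
        if not (self.mu_inc > 1 > self.mu_dec > 0):
            raise ValueError("need mu_inc > 1 > mu_dec > 0")


@dataclass
class TrainReport:
    """Per-epoch error history and stopping bookkeeping."""

    train_mse: list[float]
    val_mse: list[float]
    test_mse: list[float]
    best_epoch: int  # 1-based epoch whose parameters are returned
    stop_epoch: int
    stop_reason: str

    def export_csv(self, path: str) -> None:
        rows = np.column_stack([
            np.arange(1, len(self.train_mse) + 1),
            self.train_mse, self.val_mse, self.test_mse,
        ])
        np.savetxt(path, rows, delimiter=",", fmt="%.8g",
                   header="epoch,train_mse,val_mse,test_mse", comments="")


def _mse(net: ShallowNet, X: np.ndarray, t: np.ndarray) -> float:
    r = forward(net, X) - t
    return float(r @ r / len(r))


def train_lm(
    data: ProfileDataset,
    cfg: TrainConfig = TrainConfig(),
    net: ShallowNet | None = None,
) -> tuple[ShallowNet, TrainReport]:
    """Train the network on a split dataset; see the module docstring.

    Returns the best-validation snapshot and the epoch history.  Raises if
    any split is empty or the loss turns non-finite; damping overflow
    (``mu > mu_max`` with no acceptable step) ends training with the stop
    reason recorded, which in practice means the optimum was reached.
    """
    idx = {s: data.rows(s) for s in ("train", "val", "test")}
    for s, rows in idx.items():
        if len(rows) == 0:
            raise ValueError(f"empty {s!r} split")
    X = {s: data.features[rows] for s, rows in idx.items()}
    t = {s: data.targets[rows] for s, rows in idx.items()}

    if net is None:
        net = init_net(data.length, cfg.n_hidden, cfg.seed)
    p = net.pack()
    mu = cfg.mu_init

    hist: dict[str, list[float]] = {"train": [], "val": [], "test": []}
    best_val = np.inf
    best_p = p.copy()
    best_epoch = 0
    stall = 0
    stop_reason = "max_epochs"
    epoch = 0

    train_err = _mse(net, X["train"], t["train"])
    while epoch < cfg.max_epochs:
        r = forward(net, X["train"]) - t["train"]
        if not np.isfinite(train_err):
            raise FloatingPointError("non-finite training loss")
        J = jacobian(net, X["train"])
        jtj = J.T @ J
        jtr = J.T @ r
        n_train = len(r)

        accepted = False
        while mu <= cfg.mu_max:
            try:
                c = cho_factor(jtj + mu * np.eye(jtj.shape[0]))
                step = cho_solve(c, -jtr)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            cand = p + step
            net.unpack(cand)
            r_new = forward(net, X["train"]) - t["train"]
            new_err = float(r_new @ r_new / n_train)
            if np.isfinite(new_err) and new_err < train_err:
                p, train_err = cand, new_err
                mu = max(mu * cfg.mu_dec, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            net.unpack(p)
            stop_reason = "mu_overflow"
            break

        epoch += 1
        hist["train"].append(train_err)
        hist["val"].append(_mse(net, X["val"], t["val"]))
        hist["test"].append(_mse(net, X["test"], t["test"]))
        if hist["val"][-1] < best_val:
            best_val = hist["val"][-1]
            best_p = p.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                stop_reason = "early_stop"
                break

    net.unpack(best_p)
    net.meta.update({"n_hidden": cfg.n_hidden, "seed": cfg.seed,
                     "normalization": "per-row-minmax"})
    report = TrainReport(
        train_mse=hist["train"],
        val_mse=hist["val"],
        test_mse=hist["test"],
        best_epoch=best_epoch,
        stop_epoch=epoch,
        stop_reason=stop_reason,
    )
    logger.info("LM training stopped at epoch %d (%s); best epoch %d, "
                "val MSE %.3g", epoch, stop_reason, best_epoch, best_val)
    return net, report


@dataclass
class PredictedPositions:
    """Predictions mapped to profile indices and image coordinates."""

    fractions: np.ndarray  # raw (or clipped) network outputs
    positions_px: np.ndarray  # fraction * L, pixels along the segment
    points_xy: np.ndarray  # (n, 2) predicted edge locations in the image
    n_clipped: int = 0


def predict_positions(
    net: ShallowNet,
    dataset: ProfileDataset,
    length: int | None = None,
    clip: bool = False,
) -> PredictedPositions:
    """Map network outputs to positions along each profile and in the image.

    A fraction p becomes pixel index ``p * L`` along the sampling segment
    (an output of 0.3 with L=100 puts the edge at index 30).  The image
    location follows from the profile origin: the origin sits at fraction
    ``start_frac``, so the prediction lies ``(p - start_frac) * L`` pixels
    along the outward direction.  With ``clip=True`` raw outputs are forced
    into [0, 1] first (clip events counted).
    """
    L = length if length is not None else dataset.length
    out = forward(net, dataset.features)
    n_clipped = 0
    if clip:
        n_clipped = int(((out < 0) | (out > 1)).sum())
        if n_clipped:
            logger.info("clipped %d/%d predictions into [0, 1]", n_clipped,
                        len(out))
        out = np.clip(out, 0.0, 1.0)
    positions = out * L
    x0, y0, theta = dataset.origins.T
    dx, dy = direction_vector(theta)
    disp = (out - dataset.start_frac) * L
    points = np.column_stack([x0 + disp * dx, y0 + disp * dy])
    return PredictedPositions(fractions=out, positions_px=positions,
                              points_xy=points, n_clipped=n_clipped)


def save_net(net: ShallowNet, path: str | Path) -> None:
    """Write the network as a JSON container (bit-exact round trip)."""
    payload = {
        "format": FILE_FORMAT,
        "version": FILE_VERSION,
        "length": net.length,
        "n_hidden": net.n_hidden,
        "w_h": [[float(v).hex() for v in row] for row in net.w_h],
        "b_h": [float(v).hex() for v in net.b_h],
        "w_o": [float(v).hex() for v in net.w_o],
        "b_o": float(net.b_o).hex(),
        "meta": {k: v for k, v in net.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    Path(path).write_text(json.dumps(payload))


def load_net(path: str | Path) -> ShallowNet:
    """Load a saved network, validating format and shapes."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != FILE_FORMAT:
        raise ValueError(f"not a {FILE_FORMAT} file")
    if payload.get("version") != FILE_VERSION:
        raise ValueError(f"unsupported file version {payload.get('version')}")
    w_h = np.array([[float.fromhex(v) for v in row] for row in payload["w_h"]])
    b_h = np.array([float.fromhex(v) for v in payload["b_h"]])
    w_o = np.array([float.fromhex(v) for v in payload["w_o"]])
    b_o = float.fromhex(payload["b_o"])
    if w_h.shape != (payload["n_hidden"], payload["length"]):
        raise ValueError("parameter shapes do not match the declared sizes")
    if b_h.shape != (payload["n_hidden"],) or w_o.shape != (payload["n_hidden"],):
        raise ValueError("parameter shapes do not match the declared sizes")
    return ShallowNet(w_h, b_h, w_o, b_o, meta=payload.get("meta", {}))
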
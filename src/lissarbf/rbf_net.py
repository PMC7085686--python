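"""Radial basis function classifier on autoencoder codes.

Three-layer network: the frozen encoder's codes feed r Gaussian units

    phi_k(c) = exp(-||c - u_k||^2 / (2 sigma_k^2))

whose centers u_k come from k-means over the training codes and whose
widths sigma_k are the RMS distance of each cluster's members to its
center.  A linear output layer (with bias) regresses the activations onto
one-hot activity targets by ridge least squares; prediction is the argmax
of the linear scores.  The unit count r is chosen by a greedy sweep from
r = p (the activity count) up to floor(N/2), keeping the network with the
smallest training MSE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "RBFLayer",
    "RBFNetwork",
    "GreedySearchConfig",
    "fit_centers",
    "rbf_activations",
    "fit_output_weights",
    "network_predict",
    "training_mse",
    "greedy_search",
    "fit_rbf_network",
]

DEFAULT_RIDGE = 1e-8
FALLBACK_WIDTH = 0.1
# clusters whose members coincide to rounding have no usable spread
DEGENERATE_WIDTH = 1e-6


@dataclass(frozen=True)
class RBFLayer:
    """r Gaussian units: centers (r, h) in code space, positive widths (r,)."""

    centers: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", w)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("centers must be a nonempty (r, h) matrix")
        if w.shape != (c.shape[0],):
            raise ValueError("widths must be length r")
        if (w <= 0).any():
            raise ValueError("widths must be strictly positive")

    @property
    def r(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class RBFNetwork:
    """RBF layer plus linear one-hot output weights ((r+1, p), bias row last)."""

    layer: RBFLayer
    output_weights: np.ndarray

    def __post_init__(self) -> None:
        ow = np.asarray(self.output_weights, dtype=float)
        object.__setattr__(self, "output_weights", ow)
        if ow.shape[0] != self.layer.r + 1:
            raise ValueError("output_weights must have r+1 rows (bias row included)")

    @property
    def p(self) -> int:
        return self.output_weights.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "r": self.layer.r,
                "h": self.layer.centers.shape[1],
                "p": self.p,
                "centers": self.layer.centers.ravel().tolist(),
                "widths": self.layer.widths.tolist(),
                "output_weights": self.output_weights.ravel().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RBFNetwork":
        obj = json.loads(text)
        r, h, p = obj["r"], obj["h"], obj["p"]
        layer = RBFLayer(
            centers=np.asarray(obj["centers"]).reshape(r, h),
            widths=np.asarray(obj["widths"]),
        )
        return cls(layer=layer, output_weights=np.asarray(obj["output_weights"]).reshape(r + 1, p))


def fit_centers(codes: np.ndarray, r: int, seed: int = 0) -> RBFLayer:
    """k-means centers and RMS-distance widths over training codes.

    Seeded k-means++ init, at most 300 iterations, tolerance 1e-6.  A
    cluster that ends up empty or a singleton has no spread of its own; its
    width falls back to the mean width of the populated clusters, or 0.1
    when every cluster is degenerate.
    """
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    if r > n:
        raise ValueError(f"r={r} exceeds number of training codes {n}")
    if r < 1:
        raise ValueError("r must be positive")
    km = KMeans(n_clusters=r, init="k-means++", n_init=1, max_iter=300, tol=1e-6, random_state=seed)
    with warnings.catch_warnings():
        # fewer distinct codes than clusters is routine on near-duplicate data
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        assign = km.fit_predict(codes)
    centers = km.cluster_centers_
    widths = np.zeros(r)
    counts = np.bincount(assign, minlength=r)
    for k in range(r):
        if counts[k] >= 2:
            diff = codes[assign == k] - centers[k]
            widths[k] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    ok = widths > DEGENERATE_WIDTH
    fallback = float(widths[ok].mean()) if ok.any() else FALLBACK_WIDTH
    widths[~ok] = fallback
    return RBFLayer(centers=centers, widths=widths)


def rbf_activations(codes: np.ndarray, layer: RBFLayer) -> np.ndarray:
    """Gaussian activations exp(-||c - u_k||^2 / (2 sigma_k^2)), in (0, 1]."""
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    if codes.shape[1] != layer.centers.shape[1]:
        raise ValueError("code dimension does not match RBF centers")
    # direct differences: exactly 0 (activation exactly 1) at a center
    sq = cdist(codes, layer.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * layer.widths**2))


def _design(activations: np.ndarray) -> np.ndarray:
    return np.hstack([activations, np.ones((activations.shape[0], 1))])


def fit_output_weights(
    activations: np.ndarray,
    targets: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Ridge least-squares fit of the linear output layer.

    Minimizes ``||[Phi, 1] Theta - T||^2 + ridge ||Theta||^2``.  With
    ridge > 0 the regularized normal equations are always well posed; with
    ridge = 0 the minimum-norm least-squares solution is returned, which
    interpolates exactly whenever the (possibly rank-deficient) system is
    consistent.
    """
    activations = np.asarray(activations, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if activations.shape[0] != targets.shape[0]:
        raise ValueError("activations and targets disagree on N")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    Phi = _design(activations)
    if ridge > 0:
        G = Phi.T @ Phi + ridge * np.eye(Phi.shape[1])
        theta = np.linalg.solve(G, Phi.T @ targets)
    else:
        theta, *_ = np.linalg.lstsq(Phi, targets, rcond=None)
    if not np.isfinite(theta).all():
        raise np.linalg.LinAlgError(
            "singular output-layer system; refit with ridge > 0"
        )
    return theta


def network_predict(codes: np.ndarray, net: RBFNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Linear scores and argmax labels (ties break toward the lowest class id)."""
    act = rbf_activations(codes, net.layer)
    scores = _design(act) @ net.output_weights
    return scores, np.argmax(scores, axis=1)


def training_mse(scores: np.ndarray, targets: np.ndarray) -> float:
    """Mean over instances of the squared score-target row distance."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if scores.shape != targets.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {targets.shape}")
    diff = scores - targets
    return float(np.sum(diff * diff) / scores.shape[0])


def fit_rbf_network(
    codes: np.ndarray,
    targets: np.ndarray,
    r: int,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[RBFNetwork, float]:
    """Fit one candidate network (centers, widths, output layer); returns its training MSE."""
    layer = fit_centers(codes, r, seed=seed)
    act = rbf_activations(codes, layer)
    theta = fit_output_weights(act, targets, ridge=ridge)
    net = RBFNetwork(layer=layer, output_weights=theta)
    mse = training_mse(_design(act) @ theta, targets)
    return net, mse


@dataclass(frozen=True)
class GreedySearchConfig:
    """Candidate grid for the unit-count search.

    ``r_min``/``r_max`` default to the activity count p and floor(N/2) when
    left as None; step 1 walks the full grid, larger steps allow coarse
    sweeps.
    """

    r_min: int | None = None
    r_max: int | None = None
    step: int = 1
    seed: int = 0
    ridge: float = DEFAULT_RIDGE

    def candidates(self, n: int, p: int) -> list[int]:
        lo = self.r_min if self.r_min is not None else p
        hi = self.r_max if self.r_max is not None else n // 2
        hi = min(hi, n)
        if lo < 1:
            raise ValueError("r_min must be at least 1")
        if self.step < 1:
            raise ValueError("step must be positive")
        cand = list(range(lo, hi + 1, self.step))
        if not cand:
            raise ValueError(f"empty candidate set: r_min={lo}, r_max={hi}")
        return cand


def greedy_search(
    codes: np.ndarray,
    targets: np.ndarray,
    config: GreedySearchConfig = GreedySearchConfig(),
) -> tuple[RBFNetwork, list[tuple[int, float]]]:
    """Pick the unit count minimizing training MSE over the candidate grid.

    Trains one full network (k-means + output layer) per candidate r and
    keeps the minimum-MSE one; ties go to the smallest r.  Returns the
    winner and the (r, MSE) trace.
    """
    codes = np.asarray(codes, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n, p = targets.shape
    trace: list[tuple[int, float]] = []
    best_net, best_mse = None, np.inf
    for r in config.candidates(n, p):
        net, mse = fit_rbf_network(codes, targets, r, seed=config.seed, ridge=config.ridge)
        trace.append((r, mse))
        if mse < best_mse:  # strict: ties keep the smaller r
            best_net, best_mse = net, mse
    assert best_net is not None
    return best_net, trace


def trace_to_csv(trace: list[tuple[int, float]], path: str | Path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r", "training_mse"])
        for r, mse in trace:
            w.writerow([r, repr(float(mse))])
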
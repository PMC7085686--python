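"""Localized stochastic-sensitive autoencoder (LiSSA).

A single-hidden-layer sigmoid autoencoder

    C = sigma(X W + b1)        (encoder, d -> h)
    Y = sigma(C V + b2)        (decoder, h -> d)

is trained by full-batch gradient descent on the sum of two terms:

* the reconstruction mean squared error
  ``R = (1/N) sum_i ||Y(i) - X(i)||^2``, and
* the *stochastic sensitivity measure* (STSM): the expected squared change
  of the reconstruction when the input is perturbed anywhere inside the
  Q-neighborhood ``[x - Q, x + Q]^d``.  The expectation is estimated by
  quasi-Monte Carlo over J Halton points mapped into ``[-Q, Q]^d``:

      STSM ~= (1/(N J)) sum_i sum_j ||g(X(i)) - g(X(i) + dX_j)||^2

  where ``g`` is the full encode-decode map.

Minimizing ``R + STSM`` minimizes an upper bound on the localized
generalization error over the Q-neighborhoods of the training points, so
the learned code is deliberately insensitive to small sensor flips and
transmission noise — the failure mode binary home sensors actually exhibit.
The hidden width h is normally set *larger* than d: the encoder lifts the
binary inputs into a continuous, higher-dimensional code from which a
downstream classifier can separate activities whose raw sensor signatures
overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.stats import qmc

__all__ = [
    "AutoencoderParams",
    "PerturbationSet",
    "LiSSATrainConfig",
    "LGEBoundInputs",
    "LossHistory",
    "sigmoid",
    "ae_forward",
    "encode",
    "reconstruction_mse",
    "halton_points",
    "perturbation_set",
    "stsm",
    "lissa_objective",
    "lissa_gradient",
    "train_autoencoder",
    "lge_bound",
]


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function 1/(1+exp(-x)), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class AutoencoderParams:
    """Weights of the sigmoid autoencoder: W (d x h), b1 (h), V (h x d), b2 (d)."""

    W: np.ndarray
    b1: np.ndarray
    V: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        V = np.asarray(self.V, dtype=float)
        b2 = np.asarray(self.b2, dtype=float)
        for name, arr in (("W", W), ("b1", b1), ("V", V), ("b2", b2)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite entries in {name}")
            object.__setattr__(self, name, arr)
        d, h = W.shape
        if b1.shape != (h,) or V.shape != (h, d) or b2.shape != (d,):
            raise ValueError(
                f"inconsistent shapes: W{W.shape} b1{b1.shape} V{V.shape} b2{b2.shape}"
            )

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def h(self) -> int:
        return self.W.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "d": self.d,
                "h": self.h,
                "W": self.W.ravel().tolist(),
                "b1": self.b1.tolist(),
                "V": self.V.ravel().tolist(),
                "b2": self.b2.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AutoencoderParams":
        obj = json.loads(text)
        d, h = obj["d"], obj["h"]
        return cls(
            W=np.asarray(obj["W"]).reshape(d, h),
            b1=np.asarray(obj["b1"]),
            V=np.asarray(obj["V"]).reshape(h, d),
            b2=np.asarray(obj["b2"]),
        )


def ae_forward(X: np.ndarray, params: AutoencoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Run the encode-decode chain; returns (codes C, reconstructions Y)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.d:
        raise ValueError(f"input has {X.shape[1]} features, autoencoder expects {params.d}")
    C = sigmoid(X @ params.W + params.b1)
    Y = sigmoid(C @ params.V + params.b2)
    return C, Y


def encode(X: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Hidden codes C = sigma(X W + b1); the feature map fed to the classifier."""
    return ae_forward(X, params)[0]


def reconstruction_mse(Y: np.ndarray, X: np.ndarray) -> float:
    """R = (1/N) sum_i ||Y(i) - X(i)||^2 (squared-norm mean, not per-entry)."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape != X.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {X.shape}")
    diff = Y - X
    return float(np.sum(diff * diff) / X.shape[0])


def halton_points(J: int, d: int) -> np.ndarray:
    """First J points of the d-dimensional Halton sequence in [0, 1)^d.

    Coordinate m is the van der Corput sequence in the m-th prime base,
    started at index 1 (so d=1 begins 1/2, 1/4, 3/4, ...), unscrambled.
    """
    if J < 1 or d < 1:
        raise ValueError("J and d must be positive")
    sampler = qmc.Halton(d=d, scramble=False)
    sampler.fast_forward(1)  # drop the index-0 all-zeros point
    return sampler.random(J)


@dataclass(frozen=True)
class PerturbationSet:
    """J offsets in [-Q, Q]^d defining the Q-neighborhood QMC sample."""

    Q: float
    offsets: np.ndarray  # (J, d)

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", off)
        if self.Q < 0:
            raise ValueError("Q must be nonnegative")
        if off.ndim != 2:
            raise ValueError("offsets must be (J, d)")
        if off.size and np.abs(off).max() > self.Q + 1e-12:
            raise ValueError("offset magnitude exceeds Q")

    @property
    def J(self) -> int:
        return self.offsets.shape[0]

    @property
    def d(self) -> int:
        return self.offsets.shape[1]


def perturbation_set(Q: float, J: int, d: int) -> PerturbationSet:
    """Map Halton points affinely onto [-Q, Q]^d: offsets = 2Q*H - Q."""
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    offsets = 2.0 * Q * halton_points(J, d) - Q
    return PerturbationSet(Q=Q, offsets=offsets)


def _perturbed_forward(X: np.ndarray, params: AutoencoderParams, perts: PerturbationSet):
    """Forward pass on all J perturbed copies at once; returns (J, N, d) pieces."""
    J, N, d = perts.J, X.shape[0], X.shape[1]
    Xp = (X[None, :, :] + perts.offsets[:, None, :]).reshape(J * N, d)
    Cp = sigmoid(Xp @ params.W + params.b1)
    Yp = sigmoid(Cp @ params.V + params.b2)
    return Xp.reshape(J, N, d), Cp.reshape(J, N, params.h), Yp.reshape(J, N, d)


def stsm(
    params: AutoencoderParams,
    X: np.ndarray,
    perts: PerturbationSet,
    normalize: bool = True,
) -> float:
    """Quasi-Monte-Carlo stochastic sensitivity of the encode-decode map.

    With ``normalize=True`` (default) divides by N*J, the expectation
    estimate; ``normalize=False`` divides by N only (the raw-sum reading).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.d or perts.d != params.d:
        raise ValueError("feature dimension mismatch")
    if perts.Q == 0.0:
        return 0.0  # dX = 0 implies dY = 0 identically
    _, Y = ae_forward(X, params)
    _, _, Yp = _perturbed_forward(X, params, perts)
    diff = Y[None, :, :] - Yp
    total = float(np.sum(diff * diff))
    denom = X.shape[0] * (perts.J if normalize else 1)
    return total / denom


def lissa_objective(
    params: AutoencoderParams,
    X: np.ndarray,
    perts: PerturbationSet,
    stsm_weight: float = 1.0,
) -> float:
    """Training objective R + stsm_weight * STSM (weight 0 = plain autoencoder)."""
    _, Y = ae_forward(X, params)
    value = reconstruction_mse(Y, X)
    if stsm_weight != 0.0:
        value += stsm_weight * stsm(params, X, perts)
    return value


def lissa_gradient(
    params: AutoencoderParams,
    X: np.ndarray,
    perts: PerturbationSet,
    stsm_weight: float = 1.0,
) -> tuple[float, AutoencoderParams]:
    """Objective value and its analytic gradient (packed as AutoencoderParams).

    Gradients flow through both the clean pass g(X) and every perturbed pass
    g(X + dX_j); the sensitivity term therefore shapes the encoder, not just
    the decoder.
    """
    value, _, _, grad = _value_and_gradient(params, X, perts, stsm_weight)
    return value, grad


def _value_and_gradient(
    params: AutoencoderParams,
    X: np.ndarray,
    perts: PerturbationSet,
    stsm_weight: float,
) -> tuple[float, float, float, AutoencoderParams]:
    """(objective, R, STSM, gradient) in one pass over the data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, d = X.shape
    C = sigmoid(X @ params.W + params.b1)
    Y = sigmoid(C @ params.V + params.b2)
    diff = Y - X
    R = float(np.sum(diff * diff) / N)

    # reconstruction term backprop
    dY = (2.0 / N) * diff
    dZ2 = dY * Y * (1.0 - Y)
    gV = C.T @ dZ2
    gb2 = dZ2.sum(axis=0)
    dC = dZ2 @ params.V.T
    dZ1 = dC * C * (1.0 - C)
    gW = X.T @ dZ1
    gb1 = dZ1.sum(axis=0)
    value = R
    S = 0.0

    if stsm_weight != 0.0 and perts.Q > 0.0:
        J = perts.J
        Xp, Cp, Yp = _perturbed_forward(X, params, perts)
        D = Y[None, :, :] - Yp  # (J, N, d)
        S = float(np.sum(D * D) / (N * J))
        value += stsm_weight * S
        scale = 2.0 * stsm_weight / (N * J)
        # clean-path contribution: dS/dY = scale * sum_j D_j
        dY_s = scale * D.sum(axis=0)
        dZ2_s = dY_s * Y * (1.0 - Y)
        gV += C.T @ dZ2_s
        gb2 += dZ2_s.sum(axis=0)
        dC_s = dZ2_s @ params.V.T
        dZ1_s = dC_s * C * (1.0 - C)
        gW += X.T @ dZ1_s
        gb1 += dZ1_s.sum(axis=0)
        # perturbed-path contribution: dS/dYp_j = -scale * D_j
        JN = J * N
        Yp2 = Yp.reshape(JN, d)
        Cp2 = Cp.reshape(JN, params.h)
        Xp2 = Xp.reshape(JN, d)
        dYp = (-scale * D).reshape(JN, d)
        dZ2p = dYp * Yp2 * (1.0 - Yp2)
        gV += Cp2.T @ dZ2p
        gb2 += dZ2p.sum(axis=0)
        dCp = dZ2p @ params.V.T
        dZ1p = dCp * Cp2 * (1.0 - Cp2)
        gW += Xp2.T @ dZ1p
        gb1 += dZ1p.sum(axis=0)

    grad = AutoencoderParams(W=gW, b1=gb1, V=gV, b2=gb2)
    return value, R, S, grad


@dataclass(frozen=True)
class LiSSATrainConfig:
    """Hyperparameters of LiSSA training.

    Q is the neighborhood half-width in feature units; with binary sensors a
    default of 0.1 is a small perturbation relative to the 0/1 gap.  J=50
    Halton points estimate the sensitivity expectation.  ``stsm_weight`` is
    an ablation knob: 1 trains the full objective, 0 a plain autoencoder.
    ``hidden_units`` defaults to 20, the width that works best on most
    published binary-sensor corpora; datasets with sparse sensor coverage
    can need far more (the hidden-unit sweep exists for exactly that).
    """

    hidden_units: int = 20
    learning_rate: float = 0.05
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    seed: int = 0
    Q: float = 0.1
    J: int = 50
    stsm_weight: float = 1.0
    init_scale: float | None = None  # None -> 1/sqrt(d)

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.Q < 0:
            raise ValueError("Q must be nonnegative")
        if self.J < 1:
            raise ValueError("J must be positive")
        if self.stsm_weight < 0:
            raise ValueError("stsm_weight must be nonnegative")


class LossHistory(NamedTuple):
    """Per-epoch objective decomposition; index 0 is the initial state."""

    R: np.ndarray
    stsm: np.ndarray
    objective: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        import csv

        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "R", "STSM", "objective"])
            for e, (r, s, o) in enumerate(zip(self.R, self.stsm, self.objective)):
                w.writerow([e, repr(float(r)), repr(float(s)), repr(float(o))])


class TrainingDivergedError(RuntimeError):
    pass


def init_params(d: int, h: int, seed: int, init_scale: float | None = None) -> AutoencoderParams:
    """Seeded uniform init in [-s, s], s = init_scale or 1/sqrt(d)."""
    s = init_scale if init_scale is not None else 1.0 / math.sqrt(d)
    rng = np.random.default_rng(seed)
    return AutoencoderParams(
        W=rng.uniform(-s, s, size=(d, h)),
        b1=rng.uniform(-s, s, size=h),
        V=rng.uniform(-s, s, size=(h, d)),
        b2=rng.uniform(-s, s, size=d),
    )


def train_autoencoder(
    X: np.ndarray,
    config: LiSSATrainConfig = LiSSATrainConfig(),
) -> tuple[AutoencoderParams, LossHistory]:
    """Gradient-descent training of the LiSSA objective.

    One Halton perturbation set is drawn up front and reused for every
    instance and every epoch — the estimator's offsets carry no instance
    index, and a fixed set keeps the objective a deterministic function of
    the parameters.  Full-batch descent by default; ``batch_size`` enables
    seeded mini-batches (the loss history still records full-batch values).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, d = X.shape
    params = init_params(d, config.hidden_units, config.seed, config.init_scale)
    perts = perturbation_set(config.Q, config.J, d)
    w = config.stsm_weight

    hist_R = np.empty(config.epochs + 1)
    hist_S = np.empty(config.epochs + 1)
    hist_O = np.empty(config.epochs + 1)

    def record(epoch: int) -> None:
        _, Y = ae_forward(X, params)
        r = reconstruction_mse(Y, X)
        s = stsm(params, X, perts) if (w != 0.0 and config.Q > 0) else 0.0
        o = r + w * s
        if not math.isfinite(o):
            raise TrainingDivergedError(f"non-finite objective at epoch {epoch}")
        hist_R[epoch], hist_S[epoch], hist_O[epoch] = r, s, o

    lr = config.learning_rate
    batch_rng = np.random.default_rng(config.seed + 1) if config.batch_size else None
    for epoch in range(config.epochs):
        if config.batch_size is None:
            # full batch: the gradient pass already yields this epoch's losses
            o, r, s, grad = _value_and_gradient(params, X, perts, w)
            if not math.isfinite(o):
                raise TrainingDivergedError(f"non-finite objective at epoch {epoch}")
            hist_R[epoch], hist_S[epoch], hist_O[epoch] = r, s, o
            try:
                params = AutoencoderParams(
                    W=params.W - lr * grad.W,
                    b1=params.b1 - lr * grad.b1,
                    V=params.V - lr * grad.V,
                    b2=params.b2 - lr * grad.b2,
                )
            except ValueError as exc:  # overflowing update
                raise TrainingDivergedError(
                    f"non-finite parameters at epoch {epoch}"
                ) from exc
        else:
            record(epoch)
            order = batch_rng.permutation(N)
            for start in range(0, N, config.batch_size):
                idx = order[start : start + config.batch_size]
                _, grad = lissa_gradient(params, X[idx], perts, w)
                params = AutoencoderParams(
                    W=params.W - lr * grad.W,
                    b1=params.b1 - lr * grad.b1,
                    V=params.V - lr * grad.V,
                    b2=params.b2 - lr * grad.b2,
                )
    record(config.epochs)
    return params, LossHistory(R=hist_R, stsm=hist_S, objective=hist_O)


@dataclass(frozen=True)
class LGEBoundInputs:
    """Constants of the localized generalization error bound."""

    A: float  # maximum output difference
    B: float  # maximum possible MSE
    eta: float  # confidence parameter in (0, 1); bound holds w.p. 1 - eta
    N: int

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be nonnegative")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie strictly in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be positive")


def lge_bound(R: float, stsm_value: float, inputs: LGEBoundInputs) -> float:
    """Localized generalization error upper bound (reporting only).

    Computed as ``(sqrt(R) + sqrt(STSM) + sqrt(A))^2 + B*sqrt(ln(eta)/(-2N))``
    — the square-root composition of training error, sensitivity and the
    worst-case constants, plus the Hoeffding confidence term.  The training
    objective minimizes only R + STSM; this bound is never optimized.
    """
    if R < 0 or stsm_value < 0:
        raise ValueError("R and STSM must be nonnegative")
    core = (math.sqrt(R) + math.sqrt(stsm_value) + math.sqrt(inputs.A)) ** 2
    conf = inputs.B * math.sqrt(math.log(inputs.eta) / (-2.0 * inputs.N))
    return core + conf
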
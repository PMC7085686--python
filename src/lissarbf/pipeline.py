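"""End-to-end model, evaluation metrics and repeated cross-validation.

Training is two-step: (1) the stochastic-sensitive autoencoder is fit on
the training features alone and then frozen; (2) its codes feed the greedy
RBF unit-count search against one-hot activity targets.  Evaluation follows
the standard multi-class protocol: a p x p confusion matrix with inferred
activities on rows and actual activities on columns, per-class precision
TP_i/SI_i and recall TP_i/ST_i, per-class F1, support-weighted mean F1, and
overall accuracy; model comparison uses a two-sample t-test on per-run
metric values from repeated stratified 10-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_model import BinaryDataset, FoldPlan, make_folds, one_hot
from .lissa import AutoencoderParams, LiSSATrainConfig, LossHistory, encode, train_autoencoder
from .rbf_net import GreedySearchConfig, RBFNetwork, greedy_search, network_predict

__all__ = [
    "LiSSARBFModel",
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "train_model",
    "predict",
    "confusion",
    "precision_recall",
    "f1_per_class",
    "weighted_f1",
    "overall_accuracy",
    "metrics_report",
    "repeated_cv",
    "compare_ttest",
    "round_half_up",
]

logger = logging.getLogger("lissarbf")


# ---------------------------------------------------------------- model


@dataclass(frozen=True)
class LiSSARBFModel:
    """Frozen autoencoder + RBF classifier, with the configs that built it."""

    ae: AutoencoderParams
    net: RBFNetwork
    activity_names: tuple[str, ...]
    lissa_cfg: LiSSATrainConfig
    search_cfg: GreedySearchConfig
    loss_history: LossHistory | None = None
    search_trace: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.ae.h != self.net.layer.centers.shape[1]:
            raise ValueError("autoencoder hidden width must match RBF code dimension")

    @property
    def selected_r(self) -> int:
        return self.net.layer.r

    def to_json(self) -> str:
        return json.dumps(
            {
                "ae": json.loads(self.ae.to_json()),
                "net": json.loads(self.net.to_json()),
                "activity_names": list(self.activity_names),
                "lissa_cfg": self.lissa_cfg.__dict__,
                "search_cfg": self.search_cfg.__dict__,
                "search_trace": [list(t) for t in self.search_trace],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LiSSARBFModel":
        obj = json.loads(text)
        return cls(
            ae=AutoencoderParams.from_json(json.dumps(obj["ae"])),
            net=RBFNetwork.from_json(json.dumps(obj["net"])),
            activity_names=tuple(obj["activity_names"]),
            lissa_cfg=LiSSATrainConfig(**obj["lissa_cfg"]),
            search_cfg=GreedySearchConfig(**obj["search_cfg"]),
            search_trace=tuple((int(r), float(m)) for r, m in obj["search_trace"]),
        )


def train_model(
    dataset: BinaryDataset,
    lissa_cfg: LiSSATrainConfig = LiSSATrainConfig(),
    search_cfg: GreedySearchConfig = GreedySearchConfig(),
) -> LiSSARBFModel:
    """Two-step fit: train + freeze the autoencoder, then greedy RBF search."""
    logger.info(
        "training autoencoder: N=%d d=%d h=%d seed=%d",
        dataset.n_instances,
        dataset.n_sensors,
        lissa_cfg.hidden_units,
        lissa_cfg.seed,
    )
    ae, history = train_autoencoder(dataset.features, lissa_cfg)
    codes = encode(dataset.features, ae)
    targets = one_hot(dataset.labels, dataset.n_activities)
    net, trace = greedy_search(codes, targets, search_cfg)
    logger.info("greedy search selected r=%d over %d candidates", net.layer.r, len(trace))
    return LiSSARBFModel(
        ae=ae,
        net=net,
        activity_names=dataset.activity_names,
        lissa_cfg=lissa_cfg,
        search_cfg=search_cfg,
        loss_history=history,
        search_trace=tuple(trace),
    )


def predict(model: LiSSARBFModel, features: np.ndarray) -> np.ndarray:
    """Encode with the frozen autoencoder, classify with the RBF network."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.ae.d:
        raise ValueError(
            f"features have {features.shape[1]} sensors, model expects {model.ae.d}"
        )
    codes = encode(features, model.ae)
    _, labels = network_predict(codes, model.net)
    return labels


# ---------------------------------------------------------------- metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """p x p counts: rows = inferred activity, columns = actual activity."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if c.sum() < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def p(self) -> int:
        return self.counts.shape[0]

    @property
    def true_positives(self) -> np.ndarray:
        return np.diagonal(self.counts)

    @property
    def inferred_supports(self) -> np.ndarray:
        """SI_i: instances inferred as class i (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def true_supports(self) -> np.ndarray:
        """ST_i: instances actually of class i (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true: np.ndarray, y_pred: np.ndarray, p: int) -> ConfusionMatrix:
    """counts[i, j] = #(inferred i and actually j)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= p):
            raise ValueError(f"{name} contains ids outside 0..{p - 1}")
    counts = np.zeros((p, p), dtype=np.int64)
    np.add.at(counts, (y_pred, y_true), 1)
    return ConfusionMatrix(counts)


def precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision TP_i/SI_i and recall TP_i/ST_i.

    A class never inferred (SI_i = 0) gets precision 0; a class with no true
    instances (ST_i = 0) gets recall 0.  Both are warned about rather than
    fatal, so skewed folds still evaluate.
    """
    tp = cm.true_positives.astype(float)
    si = cm.inferred_supports
    st = cm.true_supports
    if (si == 0).any():
        warnings.warn(
            f"classes never inferred (precision set to 0): {np.flatnonzero(si == 0).tolist()}",
            stacklevel=2,
        )
    if (st == 0).any():
        warnings.warn(
            f"classes with no true instances (recall set to 0): {np.flatnonzero(st == 0).tolist()}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(si > 0, tp / np.maximum(si, 1), 0.0)
        recall = np.where(st > 0, tp / np.maximum(st, 1), 0.0)
    return precision, recall


def f1_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class harmonic mean of precision and recall (0 when both vanish)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(cm)
    denom = precision + recall
    return np.where(denom > 0, 2.0 * precision * recall / np.maximum(denom, 1e-300), 0.0)


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean F1: sum_i ST_i * F1_i / sum_i ST_i."""
    st = cm.true_supports
    return float(np.sum(st * f1_per_class(cm)) / st.sum())


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of instances on the diagonal; identical to micro-averaged recall."""
    return float(cm.true_positives.sum() / cm.total)


def round_half_up(x: float | np.ndarray) -> np.ndarray | int:
    """Round to nearest integer, halves away from zero — the report-table convention."""
    arr = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    return int(arr) if arr.ndim == 0 else arr


@dataclass(frozen=True)
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    weighted_f1: float
    accuracy: float

    def recall_percent_row(self) -> np.ndarray:
        """Per-class recall as integer percent — the 'Accuracy [%]' row of report tables."""
        return round_half_up(100.0 * self.recall)

    def to_json(self) -> str:
        return json.dumps(
            {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "weighted_f1": self.weighted_f1,
                "accuracy": self.accuracy,
            }
        )


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(cm)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1_per_class(cm),
        weighted_f1=weighted_f1(cm),
        accuracy=overall_accuracy(cm),
    )


# ---------------------------------------------------------------- cross-validation


@dataclass(frozen=True)
class CVResult:
    """Repeated k-fold outcome, metrics on the percent scale.

    ``fold_accuracy``/``fold_weighted_f1`` are (repeats, k) arrays; the
    summary means/stds are over all folds of all repeats, matching the
    "mean +/- std" presentation of repeated-CV tables.  Accuracy is also
    reported pooled over each repeat's aggregated confusion
    (``pooled_accuracy``), since per-instance pooling and fold averaging
    can differ when fold sizes do.
    """

    k: int
    repeats: int
    seed: int
    fold_accuracy: np.ndarray
    fold_weighted_f1: np.ndarray
    aggregate: ConfusionMatrix
    selected_r: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracy.std(ddof=1))

    @property
    def mean_weighted_f1(self) -> float:
        return float(self.fold_weighted_f1.mean())

    @property
    def std_weighted_f1(self) -> float:
        return float(self.fold_weighted_f1.std(ddof=1))

    @property
    def pooled_accuracy(self) -> float:
        return 100.0 * overall_accuracy(self.aggregate)

    @property
    def per_repeat_accuracy(self) -> np.ndarray:
        """Mean fold accuracy per repeat — the per-run values fed to the t-test."""
        return self.fold_accuracy.mean(axis=1)

    @property
    def per_repeat_weighted_f1(self) -> np.ndarray:
        return self.fold_weighted_f1.mean(axis=1)

    def summary(self) -> str:
        return (
            f"accuracy {self.mean_accuracy:.2f} +/- {self.std_accuracy:.2f} % | "
            f"F1 {self.mean_weighted_f1:.2f} +/- {self.std_weighted_f1:.2f} % "
            f"({self.k}-fold x {self.repeats})"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "repeats": self.repeats,
                "seed": self.seed,
                "fold_accuracy_pct": self.fold_accuracy.tolist(),
                "fold_weighted_f1_pct": self.fold_weighted_f1.tolist(),
                "mean_accuracy_pct": self.mean_accuracy,
                "std_accuracy_pct": self.std_accuracy,
                "mean_weighted_f1_pct": self.mean_weighted_f1,
                "std_weighted_f1_pct": self.std_weighted_f1,
                "pooled_accuracy_pct": self.pooled_accuracy,
                "aggregate_confusion": self.aggregate.counts.tolist(),
                "selected_r": self.selected_r.tolist(),
            }
        )


def repeated_cv(
    dataset: BinaryDataset,
    lissa_cfg: LiSSATrainConfig = LiSSATrainConfig(),
    search_cfg: GreedySearchConfig = GreedySearchConfig(),
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    stratified: bool = True,
    fold_plan: FoldPlan | None = None,
) -> CVResult:
    """Repeated stratified k-fold evaluation of the full two-step pipeline.

    Every fold retrains everything (autoencoder and greedy RBF search) on
    the k-1 training folds and evaluates on the held-out fold.  Deterministic
    given ``seed``, which also reseeds the stage seeds per fold.
    """
    plan = fold_plan or make_folds(dataset, k=k, repeats=repeats, seed=seed, stratified=stratified)
    p = dataset.n_activities
    targets_all = dataset.labels
    fold_acc = np.empty((plan.repeats, plan.k))
    fold_f1 = np.empty((plan.repeats, plan.k))
    selected_r = np.empty((plan.repeats, plan.k), dtype=np.int64)
    agg = np.zeros((p, p), dtype=np.int64)
    fold_seeds = np.random.SeedSequence(seed).generate_state(plan.repeats * plan.k) % (2**31)
    for rep in range(plan.repeats):
        for fold in range(plan.k):
            fs = int(fold_seeds[rep * plan.k + fold])
            tr = plan.train_indices(rep, fold)
            te = plan.test_indices(rep, fold)
            subset = BinaryDataset(
                dataset.features[tr],
                targets_all[tr],
                dataset.sensor_names,
                dataset.activity_names,
            )
            model = train_model(
                subset,
                replace(lissa_cfg, seed=fs),
                replace(search_cfg, seed=fs),
            )
            y_pred = predict(model, dataset.features[te])
            cm = confusion(targets_all[te], y_pred, p)
            fold_acc[rep, fold] = 100.0 * overall_accuracy(cm)
            fold_f1[rep, fold] = 100.0 * weighted_f1(cm)
            selected_r[rep, fold] = model.selected_r
            agg += cm.counts
            logger.info(
                "repeat %d fold %d: r=%d acc=%.2f%%",
                rep,
                fold,
                model.selected_r,
                fold_acc[rep, fold],
            )
    return CVResult(
        k=plan.k,
        repeats=plan.repeats,
        seed=seed,
        fold_accuracy=fold_acc,
        fold_weighted_f1=fold_f1,
        aggregate=ConfusionMatrix(agg),
        selected_r=selected_r,
    )


# ---------------------------------------------------------------- comparison


def compare_ttest(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    alpha: float = 0.05,
    pooled: bool = False,
) -> tuple[float, float, bool]:
    """Two-sample t-test on per-run metric values from repeated CV.

    Welch's unequal-variance form by default (``pooled=True`` for the
    classical pooled-variance test).  Returns (t, p, significant at alpha).
    Degenerate zero-variance inputs with equal means give t=0, p=1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per side")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, True
    t, pval = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(pval), bool(pval < alpha)
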
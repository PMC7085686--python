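"""Dataset container, file I/O, label encoding and cross-validation plans.

An activity-recognition dataset here is a table of *activity instances*:
one row per instance, one binary column per home-embedded sensor
(1 = the sensor was activated during the instance, 0 = it was not), and a
final categorical column naming the activity performed.  Typical published
smart-home corpora at this granularity have a few hundred instances,
10-21 sensors and 7-11 activity types.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "BinaryDataset",
    "FoldPlan",
    "load_dataset",
    "write_dataset",
    "one_hot",
    "make_folds",
]

LABEL_COLUMN = "activity"


@dataclass(frozen=True)
class BinaryDataset:
    """N x d binary sensor matrix with integer activity labels.

    Attributes
    ----------
    features : (N, d) ndarray of {0, 1}, one column per sensor.
    labels : (N,) ndarray of class ids in ``{0..p-1}``.
    sensor_names : d sensor column names.
    activity_names : p activity names; ``labels`` index into this list.
    """

    features: np.ndarray
    labels: np.ndarray
    sensor_names: tuple[str, ...]
    activity_names: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = np.asarray(self.features)
        labs = np.asarray(self.labels)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs)
        object.__setattr__(self, "sensor_names", tuple(self.sensor_names))
        object.__setattr__(self, "activity_names", tuple(self.activity_names))
        if feats.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = feats.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one instance and one sensor")
        if not np.isin(feats, (0, 1)).all():
            bad = np.argwhere(~np.isin(feats, (0, 1)))[0]
            raise ValueError(
                f"non-binary feature value at row {bad[0]}, column {bad[1]}"
            )
        if labs.shape != (n,):
            raise ValueError("labels must be a length-N vector")
        p = len(self.activity_names)
        if p < 2:
            raise ValueError("need at least two activity types")
        if labs.min() < 0 or labs.max() >= p:
            raise ValueError("labels reference undeclared activities")
        if len(self.sensor_names) != d:
            raise ValueError("sensor_names length must equal feature count")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.features.shape[1]

    @property
    def n_activities(self) -> int:
        return len(self.activity_names)

    def class_supports(self) -> np.ndarray:
        """True-instance count per activity (the ST_i of a perfect confusion)."""
        return np.bincount(self.labels, minlength=self.n_activities)


def load_dataset(path: str | Path, delimiter: str | None = None) -> BinaryDataset:
    """Read a delimited-text dataset: header, d 0/1 columns, then ``activity``.

    Labels are mapped to integer ids in first-appearance order, which keeps
    the encoding deterministic without an external schema.  The delimiter is
    auto-detected between comma and tab when not given.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        header = text.splitlines()[0] if text else ""
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row plus at least one instance")
    header_row = [c.strip() for c in rows[0]]
    sensor_names = header_row[:-1]
    d = len(sensor_names)
    features = np.empty((len(rows) - 1, d), dtype=np.int8)
    label_strings: list[str] = []
    for i, row in enumerate(rows[1:]):
        if len(row) != d + 1:
            raise ValueError(f"{path}: row {i} has {len(row)} fields, expected {d + 1}")
        for j, cell in enumerate(row[:d]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary feature value {cell!r} at row {i}, column {j}"
                )
            features[i, j] = int(cell)
        label = row[d].strip()
        if not label:
            raise ValueError(f"{path}: empty activity label at row {i}")
        label_strings.append(label)
    activity_names: list[str] = []
    index: dict[str, int] = {}
    for s in label_strings:
        if s not in index:
            index[s] = len(activity_names)
            activity_names.append(s)
    if len(activity_names) < 2:
        raise ValueError(f"{path}: need at least two activity types, found {activity_names}")
    labels = np.array([index[s] for s in label_strings], dtype=np.int64)
    return BinaryDataset(features, labels, tuple(sensor_names), tuple(activity_names))


def write_dataset(dataset: BinaryDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write the CSV/TSV dialect that :func:`load_dataset` reads back bit-exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(dataset.sensor_names) + [LABEL_COLUMN])
        for x, y in zip(dataset.features, dataset.labels):
            writer.writerow([int(v) for v in x] + [dataset.activity_names[y]])


def one_hot(labels: Sequence[int] | np.ndarray, p: int) -> np.ndarray:
    """Encode class ids as an N x p one-hot target matrix.

    Column sums of the result equal the class supports ST_i, which is what
    makes the one-hot layer the regression target of the linear output layer.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    if labels.size and (labels.min() < 0 or labels.max() >= p):
        raise ValueError(f"label id out of range for p={p}")
    targets = np.zeros((labels.size, p))
    targets[np.arange(labels.size), labels] = 1.0
    return targets


@dataclass(frozen=True)
class FoldPlan:
    """Repeated k-fold assignment: ``assignments[rep][i]`` is instance i's fold."""

    k: int
    repeats: int
    assignments: np.ndarray  # (repeats, N) fold ids in {0..k-1}
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=np.int64)
        object.__setattr__(self, "assignments", a)
        if a.shape != (self.repeats, a.shape[1]):
            raise ValueError("assignments must be (repeats, N)")
        if a.min() < 0 or a.max() >= self.k:
            raise ValueError("fold ids out of range")

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "repeats": self.repeats,
                "seed": self.seed,
                "stratified": self.stratified,
                "assignments": self.assignments.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        obj = json.loads(text)
        return cls(
            k=obj["k"],
            repeats=obj["repeats"],
            assignments=np.asarray(obj["assignments"]),
            seed=obj["seed"],
            stratified=obj["stratified"],
        )


def make_folds(
    dataset: BinaryDataset,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldPlan:
    """Build a repeated k-fold plan over the dataset's instances.

    Stratified by default so per-fold class proportions track the dataset's
    (skewed supports are the norm in these corpora); plain shuffled k-fold
    available via ``stratified=False``.  Deterministic given ``seed``; each
    repeat reshuffles with a seed derived from it.
    """
    n = dataset.n_instances
    if k > n:
        raise ValueError(f"k={k} exceeds instance count N={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    rep_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    if stratified and int(dataset.class_supports().min()) < k:
        # supports do not permit stratification at this k
        warnings.warn(
            "least-populated activity has fewer instances than k; "
            "falling back to plain shuffled k-fold",
            stacklevel=2,
        )
        stratified = False
    assignments = np.empty((repeats, n), dtype=np.int64)
    for rep in range(repeats):
        rs = int(rep_seeds[rep])
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            splits = splitter.split(dataset.features, dataset.labels)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
            splits = splitter.split(dataset.features)
        for fold, (_, test_idx) in enumerate(splits):
            assignments[rep, test_idx] = fold
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed, stratified=stratified)
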
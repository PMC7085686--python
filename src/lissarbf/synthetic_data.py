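"""Synthetic binary smart-home activity datasets.

Emulates the per-instance binary corpora used in home-based activity
recognition (a few hundred instances, 10-21 binary sensors, 7-11 activity
types): each activity has a fixed binary *prototype* — the set of sensors
that activity characteristically triggers — and every generated instance
is its class prototype with independent per-bit flips at rate rho,
modelling unreliable sensors (transmission errors, missed or spurious
activations).  Pairs of activities can be *aliased* onto one shared
prototype, reproducing the breakfast/lunch/dinner/snack ambiguity where
different activities interact with the environment identically; no
classifier can separate aliased classes from the sensor vector alone.

Time-stamped event streams, durations and activity ordering are out of
scope: instances are exchangeable rows, as in the per-instance corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import BinaryDataset

__all__ = ["GeneratorConfig", "make_prototypes", "generate_dataset", "inject_faults"]

_MAX_PROTOTYPE_TRIES = 1000


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror a mid-size published corpus: 12 sensors, 9 activity
    types, 27 instances per class (N = 243), prototypes activating ~40% of
    sensors, and a 5% per-bit flip rate — noticeable sensor unreliability
    without washing out class structure.  ``n_per_class`` may be a sequence
    to produce skewed supports or an exact total.  ``asymmetric_noise``
    flips only 1 -> 0 (missed activations) instead of both directions.
    """

    d: int = 12
    p: int = 9
    n_per_class: int | tuple[int, ...] = 27
    prototype_density: float = 0.4
    flip_prob: float = 0.05
    aliased_pairs: tuple[tuple[int, int], ...] = ()
    asymmetric_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1 or self.p < 1:
            raise ValueError("d and p must be positive")
        if not (0.0 <= self.flip_prob <= 0.5):
            raise ValueError("flip_prob must lie in [0, 0.5]")
        if not (0.0 < self.prototype_density < 1.0):
            raise ValueError("prototype_density must lie in (0, 1)")
        counts = self.per_class_counts()
        if any(c < 1 for c in counts):
            raise ValueError("every class needs at least one instance")
        for a, b in self.aliased_pairs:
            if not (0 <= a < self.p and 0 <= b < self.p) or a == b:
                raise ValueError(f"invalid aliased pair ({a}, {b})")

    def per_class_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.p
        counts = tuple(int(c) for c in self.n_per_class)
        if len(counts) != self.p:
            raise ValueError("n_per_class sequence must have length p")
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "d": self.d,
                "p": self.p,
                "n_per_class": list(self.per_class_counts()),
                "prototype_density": self.prototype_density,
                "flip_prob": self.flip_prob,
                "aliased_pairs": [list(pr) for pr in self.aliased_pairs],
                "asymmetric_noise": self.asymmetric_noise,
                "seed": self.seed,
            }
        )


def make_prototypes(config: GeneratorConfig) -> np.ndarray:
    """Draw p binary prototypes of length d.

    Non-aliased prototypes are forced pairwise distinct by rejection
    sampling (up to 1000 redraws); members of an aliased pair share one
    vector exactly.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    alias_of: dict[int, int] = {}
    for a, b in config.aliased_pairs:
        lo, hi = min(a, b), max(a, b)
        alias_of[hi] = alias_of.get(lo, lo)
    prototypes = np.zeros((config.p, config.d), dtype=np.int8)
    seen: set[bytes] = set()
    for k in range(config.p):
        if k in alias_of:
            prototypes[k] = prototypes[alias_of[k]]
            continue
        for _ in range(_MAX_PROTOTYPE_TRIES):
            cand = (rng.random(config.d) < config.prototype_density).astype(np.int8)
            if cand.tobytes() not in seen:
                prototypes[k] = cand
                seen.add(cand.tobytes())
                break
        else:
            raise RuntimeError(
                f"could not draw {config.p} distinct prototypes in {config.d} "
                "dimensions; increase d or reduce p"
            )
    return prototypes


def generate_dataset(config: GeneratorConfig) -> BinaryDataset:
    """Generate the labeled corpus: prototype per class + per-bit flips at rho."""
    prototypes = make_prototypes(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    counts = config.per_class_counts()
    rows, labels = [], []
    for k, n_k in enumerate(counts):
        block = np.repeat(prototypes[k][None, :], n_k, axis=0)
        flips = rng.random(block.shape) < config.flip_prob
        if config.asymmetric_noise:
            flips &= block == 1  # missed activations only
        block = np.where(flips, 1 - block, block)
        rows.append(block)
        labels.extend([k] * n_k)
    features = np.vstack(rows).astype(np.int8)
    sensor_names = tuple(f"sensor_{j}" for j in range(config.d))
    activity_names = tuple(f"activity_{k}" for k in range(config.p))
    return BinaryDataset(features, np.asarray(labels), sensor_names, activity_names)


def inject_faults(dataset: BinaryDataset, fault_prob: float, seed: int = 0) -> BinaryDataset:
    """Flip each sensor bit independently with ``fault_prob``; labels untouched.

    Returns a new dataset; the input is not modified.  fault_prob=1 yields
    the exact bitwise complement.
    """
    if not (0.0 <= fault_prob <= 1.0):
        raise ValueError("fault_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(dataset.features.shape) < fault_prob
    features = np.where(flips, 1 - dataset.features, dataset.features).astype(np.int8)
    return BinaryDataset(
        features, dataset.labels.copy(), dataset.sensor_names, dataset.activity_names
    )
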
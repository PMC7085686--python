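import logging

import numpy as np
import pytest

import lissarbf as lr

logging.getLogger("lissarbf").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def separable_dataset() -> lr.BinaryDataset:
    """Zero-noise corpus with distinct prototypes: every class is recoverable."""
    cfg = lr.GeneratorConfig(
        d=12, p=6, n_per_class=(34, 34, 33, 33, 33, 33), flip_prob=0.0, seed=7
    )
    return lr.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset() -> lr.BinaryDataset:
    """Small corpus with 5% sensor flips, the generator's default noise level."""
    cfg = lr.GeneratorConfig(d=10, p=5, n_per_class=20, flip_prob=0.05, seed=3)
    return lr.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_ae() -> lr.AutoencoderParams:
    """Fixed small autoencoder (d=4, h=6) for estimator-level checks."""
    rng = np.random.default_rng(42)
    return lr.AutoencoderParams(
        W=rng.normal(scale=0.8, size=(4, 6)),
        b1=rng.normal(scale=0.3, size=6),
        V=rng.normal(scale=0.8, size=(6, 4)),
        b2=rng.normal(scale=0.3, size=4),
    )


@pytest.fixture(scope="session")
def quick_train_cfg() -> lr.LiSSATrainConfig:
    """Short LiSSA schedule for pipeline-level tests where full training is overkill."""
    return lr.LiSSATrainConfig(hidden_units=12, epochs=80, seed=5)
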
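"""Shared fixtures: small synthetic configurations and one trained model.

Heavy artifacts (the benchmark training runs) are session-scoped so the
whole suite trains each model exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ieegart.cnn_model import ModelConfig
from ieegart.core import ClassLabel, SPECIALIZED_CLASSES
from ieegart.synthgen import SynthConfig
from ieegart.validation import make_benchmark_data, synthetic_training_benchmark


@pytest.fixture
def synth_cfg() -> SynthConfig:
    return SynthConfig(rng_seed=1234)


@pytest.fixture
def tiny_model_cfg() -> ModelConfig:
    """A miniature architecture for fast structural / gradient tests."""
    return ModelConfig(
        n_classes=3,
        conv_blocks=((3, 5, 2), (4, 3, 2)),
        input_stride=2,
        dense_units=6,
        dropout_rate=0.0,
        l2_lambda=1e-3,
        input_rows=2,
        input_samples=24,
    )


@pytest.fixture(scope="session")
def training_benchmark() -> dict:
    """The standard 4-class synthetic study run (3 training seeds).

    Shared by the classifier-quality check and by tests that need a
    well-trained full-size model (translation tolerance, end-to-end
    detection).
    """
    return synthetic_training_benchmark(1)


@pytest.fixture(scope="session")
def trained_model(training_benchmark):
    """The first trained full-size 4-class model of the benchmark."""
    return training_benchmark["models"][0]
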
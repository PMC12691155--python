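"""Shared fixtures. The heavyweight synthetic dataset is session-scoped so
the preprocessing-robustness and end-to-end tests share one rendering pass."""

from __future__ import annotations

import numpy as np
import pytest

from ovoscope.preprocess import PreprocessConfig, preprocess_pipeline
from ovoscope.synthetic import ClassLabel, GeneratorParams, generate_dataset

CLASS_TO_INDEX = {"unfertilized": 0, "live": 1, "abnormal": 2}


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def dataset300(default_params):
    """300 synthetic samples, 100 per class, under the default study
    conditions (disjoint palettes, mild noise)."""
    samples, manifest = generate_dataset(
        {"unfertilized": 100, "live": 100, "abnormal": 100},
        default_params, seed=20_260_923,
    )
    return samples, manifest


@pytest.fixture(scope="session")
def crops96(dataset300):
    """The dataset300 images preprocessed to 96x96 crops, as (X, y) arrays."""
    samples, _ = dataset300
    cfg = PreprocessConfig(input_size=96)
    images, labels = [], []
    for s in samples:
        result = preprocess_pipeline(s.image, cfg)
        images.append(result.image.transpose(2, 0, 1).astype(np.float32))
        labels.append(CLASS_TO_INDEX[s.label.value])
    return np.stack(images), np.asarray(labels)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
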
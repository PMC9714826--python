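"""Shared fixtures: all test data is generated, nothing is stored."""

import numpy as np
import pytest

from strokeloc import deep, ensemble as ens, features as feat, phantom as ph
from strokeloc import pipeline as pl


@pytest.fixture(scope="session")
def medium_case():
    """One 96x96 medium-contrast phantom case."""
    spec = ph._case_spec(424242, "left", "medium", 4, (96, 96), (128, 128))
    return ph.generate_phantom(spec)


@pytest.fixture(scope="session")
def easy_case():
    spec = ph._case_spec(90909, "right", "easy", 4, (96, 96), (128, 128))
    return ph.generate_phantom(spec)


def small_config():
    """Reduced pipeline configuration for fast unit-level training."""
    return pl.PipelineConfig(
        feature_config=feat.FeatureConfig(scales=(8, 16)),
        extractor_specs=(
            deep.FeatureExtractorSpec("f1", width=4, seed=11),
            deep.FeatureExtractorSpec("f2", width=5, seed=22),
            deep.FeatureExtractorSpec("f3", width=6, seed=33),
        ),
        extractor_train=deep.ExtractorTrainConfig(steps=25, batch=4),
        pixelnet_train=feat.PixelNetConfig(epochs=40, max_samples=4000),
        ensemble_train=ens.EnsembleTrainConfig(steps=20, batch=3),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Three small easy phantoms for harness-level tests."""
    cases, manifest = ph.generate_dataset(
        3, "easy", master_seed=5, n_slices=3, image_shape=(64, 64),
        label_shape=(88, 88))
    return cases, manifest


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    cases, _ = small_dataset
    cfg = small_config()
    preps = [pl.prepare_phantom_case(c, cfg, case_id=str(i))
             for i, c in enumerate(cases)]
    return preps, [c.truth for c in cases], cfg
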
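"""Shared fixtures: small synthetic datasets and a compact training config.

The training configuration used throughout the tests scales the published
architecture down to the synthetic fixtures' dimensionality (~100 features),
keeping full-suite runtime reasonable on one CPU without changing any part of
the method itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import scecda as sce

# narrow layers sized to ~100-feature fixtures; all stages identical otherwise
SMALL_TRAIN_KWARGS = dict(
    pretrain_epochs=40,
    train_epochs=100,
    hidden_dims=32,
    encoder_widths=(256,),
    batch_size=256,
    lr=5e-4,
    pretrain_lr=1e-3,
)

HIGH_SEPARATION = 10.0


def small_train_config(seed: int, **overrides) -> sce.TrainConfig:
    kwargs = {**SMALL_TRAIN_KWARGS, **overrides}
    return sce.TrainConfig(seed=seed, **kwargs)


def preprocess_layers(layers):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            sce.preprocess(layer, n_hvg=min(80, layer.m)) for layer in layers
        ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def paired_dataset():
    """Two informative modalities, three well-separated clusters."""
    cfg = sce.SynthConfig(
        n_cells=400, n_types=3, separation=HIGH_SEPARATION, seed=11
    )
    layers, truth = sce.generate(cfg)
    return layers, truth


@pytest.fixture(scope="session")
def preprocessed_dataset(paired_dataset):
    layers, truth = paired_dataset
    return preprocess_layers(layers), truth


@pytest.fixture(scope="session")
def small_fitted_model(preprocessed_dataset):
    """One fitted model reused by the cheaper integration tests."""
    layers, truth = preprocessed_dataset
    cfg = small_train_config(seed=11, pretrain_epochs=20, train_epochs=30)
    model = sce.fit(layers, 3, cfg)
    return model, layers, truth
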
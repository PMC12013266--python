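"""Shared fixtures.

The expensive artifacts (a trained diffusion generator and trained strength
predictors on the standard synthetic dataset) are session-scoped so the
recovery tests and the mutagenesis tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from promodiff.diffusion import DiffusionConfig, train_ddpm
from promodiff.fixtures import FixtureSpec, generate_fixture
from promodiff.predictor import (
    PredictorConfig,
    train_cnn_baseline,
    train_predictor,
)
from promodiff.sequence_codec import (
    PromoterDataset,
    PromoterRecord,
    split_dataset,
)

#: Standard study conditions: 2,000 50-nt sequences with planted −10/−35
#: motifs over an AT-rich background and the default strength law.
STANDARD_SPEC = FixtureSpec(count=2000, length=50, seed=1)

#: Training settings used by the desk-scale recovery tests.
DDPM_CONFIG = DiffusionConfig(T=200, epochs=100, batch_size=128, checkpoint_every=25, seed=0)
PREDICTOR_CONFIG = PredictorConfig(epochs=15, seed=0)


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return STANDARD_SPEC


@pytest.fixture(scope="session")
def fixture_dataset(fixture_spec) -> PromoterDataset:
    return generate_fixture(fixture_spec)


@pytest.fixture(scope="session")
def fixture_split(fixture_dataset):
    return split_dataset(fixture_dataset, test_fraction=0.2, seed=0)


@pytest.fixture(scope="session")
def small_dataset() -> PromoterDataset:
    """A fast 200-record dataset for plumbing tests."""
    return generate_fixture(FixtureSpec(count=200, seed=3))


@pytest.fixture(scope="session")
def ddpm_generator(fixture_dataset):
    return train_ddpm(fixture_dataset, DDPM_CONFIG)


@pytest.fixture(scope="session")
def ddpm_samples(ddpm_generator) -> list[str]:
    return ddpm_generator.sample(1000, seed=7)


@pytest.fixture(scope="session")
def transformer_model(fixture_split):
    train, _ = fixture_split
    return train_predictor(train, PREDICTOR_CONFIG)


@pytest.fixture(scope="session")
def cnn_model(fixture_split):
    train, _ = fixture_split
    return train_cnn_baseline(train, PREDICTOR_CONFIG)


@pytest.fixture(scope="session")
def null_transformer(fixture_split):
    """Transformer trained on label-shuffled data: the no-signal control."""
    train, _ = fixture_split
    rng = np.random.default_rng(99)
    strengths = train.strengths
    shuffled = strengths[rng.permutation(len(strengths))]
    scrambled = PromoterDataset(
        [
            PromoterRecord(r.id, r.sequence, float(s))
            for r, s in zip(train, shuffled)
        ]
    )
    return train_predictor(scrambled, PREDICTOR_CONFIG)
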
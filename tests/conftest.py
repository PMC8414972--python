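"""Shared fixtures: the synthetic image set and the trained networks that
several test modules (and the acceptance suite) analyse.

Training fixtures are session-scoped so each network is trained once per
test run.  All randomness is seeded; the fixture image set uses generator
seed 0 and the held-out evaluation set seed 100; denoising noise uses
dataset seeds 1 (train) and 2 (held-out)."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from spikeae.encoding import make_denoising_dataset
from spikeae.network import NetworkSpec
from spikeae.synthetic_data import FixtureSpec, generate
from spikeae.training import TrainConfig, default_model_params, train

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

FIXTURE_EPOCHS = 100  # the published training length


@pytest.fixture(scope="session")
def fixture_images():
    images, labels = generate(FixtureSpec(size=8, n_images=64, seed=0))
    return images, labels


@pytest.fixture(scope="session")
def holdout_images():
    images, labels = generate(FixtureSpec(size=8, n_images=64, seed=100))
    return images, labels


def _train_run(images, h, eta, latency, seed, epochs=FIXTURE_EPOCHS, n_pulses=10, long=False):
    params = default_model_params(long_latency=long)
    spec = NetworkSpec([images.shape[1] * images.shape[2], h, images.shape[1] * images.shape[2]], n_pulses, params)
    ds = make_denoising_dataset(images, eta=eta, seed=1)
    if long:
        cfg = TrainConfig.long_latency(latency=latency, epochs=epochs, seed=seed)
    else:
        cfg = TrainConfig(latency=latency, epochs=epochs, seed=seed)
    result = train(spec, ds, cfg)
    return SimpleNamespace(
        spec=spec, layers=result.layers, history=result.history, dataset=ds, config=cfg
    )


@pytest.fixture(scope="session")
def trained_denoise(fixture_images):
    """h=4 autoencoder trained on the noisy (eta=0.2) fixture task, l=1."""
    images, _ = fixture_images
    return _train_run(images, h=4, eta=0.2, latency=1.0, seed=0)


@pytest.fixture(scope="session")
def trained_clean(fixture_images):
    """h=4 autoencoder trained on the clean (eta=0) fixture task, l=1."""
    images, _ = fixture_images
    return _train_run(images, h=4, eta=0.0, latency=1.0, seed=0)


@pytest.fixture(scope="session")
def long_latency_runs(fixture_images):
    """Three seeds of the l=8 clean fixture task with the long-latency preset."""
    images, _ = fixture_images
    return [
        _train_run(images, h=4, eta=0.0, latency=8.0, seed=s, n_pulses=8, long=True)
        for s in (0, 1, 2)
    ]


@pytest.fixture(scope="session")
def trend_runs(fixture_images):
    """Seed-replicated runs over the (h, eta) grid used for trend checks."""
    images, _ = fixture_images
    grid = {}
    for h, eta in [(4, 0.0), (2, 0.0), (4, 0.4)]:
        grid[(h, eta)] = [
            _train_run(images, h=h, eta=eta, latency=1.0, seed=s) for s in (0, 1, 2)
        ]
    return grid
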
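"""Shared fixtures: desk-scale datasets and trained models for acceptance tests.

Training is the expensive step, so every trained model is a session-scoped
fixture shared by all tests that need it.  The configurations here are the
package's desk-scale study conditions (see docs/methods.md): the benchmark
keeps the full-scale data-generating conditions (70-bin segments, 12
neurons, scaled-sigmoid embedding, ~0.5 spikes/bin) with a reduced trial
count and training budget so a complete run stays within minutes per model
on one core.
"""

import numpy as np
import pytest

from flownode.model import ModelConfig, train_model
from flownode.synth import generate_dataset

DATA_SEED = 1
N_TRIALS = 400

TRAIN_KW = dict(encoder_hidden=64, node_hidden_layers=(64, 64),
                readout_hidden_layers=(64, 64), learning_rate=5e-3,
                batch_size=64, dtype="float32")


def desk_config(n_neurons, readout, d_hat, epochs, seed=0, **overrides):
    kw = {**TRAIN_KW, **overrides}
    decay = (int(epochs * 0.7), int(epochs * 0.9))
    return ModelConfig(n_neurons=n_neurons, d_hat=d_hat, readout=readout,
                       epochs=epochs, lr_decay_epochs=decay, seed=seed, **kw)


@pytest.fixture(scope="session")
def sigmoid_dataset():
    """Arneodo latents, scaled-sigmoid embedding, 12 Poisson neurons."""
    return generate_dataset(n_trials=N_TRIALS, seed=DATA_SEED)


@pytest.fixture(scope="session")
def default_sigmoid_dataset():
    """The benchmark at its default trial count (1175)."""
    return generate_dataset(seed=DATA_SEED)


@pytest.fixture(scope="session")
def flow_d3_default(default_sigmoid_dataset):
    """Flow model at the true latent dimensionality on the default-size
    benchmark; epoch budget sized for a CPU desk run."""
    return _train(default_sigmoid_dataset, "flow", 3, epochs=90)


@pytest.fixture(scope="session")
def linear_embedded_dataset():
    """Arneodo latents with log-rates affine in the latents."""
    return generate_dataset(n_trials=N_TRIALS, seed=DATA_SEED,
                            activation="lin_exp")


def _train(dataset, readout, d_hat, epochs, seed=0, **overrides):
    cfg = desk_config(dataset.n_neurons, readout, d_hat, epochs, seed=seed,
                      **overrides)
    return train_model(dataset, cfg)


@pytest.fixture(scope="session")
def flow_d3(sigmoid_dataset):
    return _train(sigmoid_dataset, "flow", 3, epochs=350)


@pytest.fixture(scope="session")
def mlp_d3(sigmoid_dataset):
    return _train(sigmoid_dataset, "mlp", 3, epochs=300)


@pytest.fixture(scope="session")
def linear_d3(sigmoid_dataset):
    return _train(sigmoid_dataset, "linear", 3, epochs=300)


@pytest.fixture(scope="session")
def flow_d10(sigmoid_dataset):
    return _train(sigmoid_dataset, "flow", 10, epochs=250)


@pytest.fixture(scope="session")
def mlp_d10(sigmoid_dataset):
    return _train(sigmoid_dataset, "mlp", 10, epochs=250)


@pytest.fixture(scope="session")
def linear_d10_linexp(linear_embedded_dataset):
    return _train(linear_embedded_dataset, "linear", 10, epochs=300)
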
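"""Shared fixtures: synthetic datasets and trained models reused across tests.

The two trained-model fixtures are session-scoped because training, while
fast, is the dominant cost; every test sees the same deterministic
artifacts (fixed seeds throughout).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from zdnapred import (
    BEST_CNN_SPEC,
    INTERPRETATION_CNN_SPEC,
    SyntheticConfig,
    TrainOptions,
    generate,
    load_energy_table,
)
from zdnapred import dataset, features, model_zoo

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def energy_table():
    return load_energy_table()


def _labels_for(data):
    return {
        c: features.label_track(data.labels, n, c)
        for c, n in data.chrom_lengths.items()
    }


@pytest.fixture(scope="session")
def default_fixture(energy_table):
    """Default synthetic study conditions: 3 x 100 kb, 12 regions,
    4 informative + 8 noise tracks, 10% peak dropout."""
    data = generate(SyntheticConfig(seed=1))
    store = features.build_store(data.genome, data.marker_tracks, energy_table)
    labels = _labels_for(data)
    ws = dataset.tile_and_select(labels, 5000, 3, seed=0)
    ws = dataset.stratified_split(ws, 0.8, seed=0)
    return {"data": data, "store": store, "labels": labels, "ws": ws}


@pytest.fixture(scope="session")
def recovery_model(default_fixture):
    """Reference CNN trained on the default fixture (30 epochs)."""
    return model_zoo.train(
        BEST_CNN_SPEC,
        default_fixture["ws"],
        default_fixture["store"],
        default_fixture["labels"],
        opts=TrainOptions(epochs=30),
        seed=0,
    )


@pytest.fixture(scope="session")
def motif_fixture():
    """Sequence-driven fixture: planted alternating-GC regions, no omics
    tracks, so the model must learn the motif from the one-hot channels."""
    data = generate(
        SyntheticConfig(
            n_chromosomes=2,
            chromosome_length=50_000,
            n_regions=16,
            region_min_separation=800,
            n_informative_tracks=0,
            n_noise_tracks=0,
            planted_motif="GC",
            seed=7,
        )
    )
    store = features.build_store(data.genome)  # one-hot channels only
    labels = _labels_for(data)
    ws = dataset.tile_and_select(labels, 1000, 3, seed=0)
    ws = dataset.stratified_split(ws, 0.8, seed=0)
    return {"data": data, "store": store, "labels": labels, "ws": ws}


@pytest.fixture(scope="session")
def motif_model(motif_fixture):
    """Two-layer kernel-5 CNN (receptive field 9) fitted to the motif fixture."""
    return model_zoo.train(
        INTERPRETATION_CNN_SPEC,
        motif_fixture["ws"],
        motif_fixture["store"],
        motif_fixture["labels"],
        opts=TrainOptions(epochs=40, batch_size=8),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_linear_model(weights: np.ndarray, channel_names: list[str]):
    """Hand-built linear scorer: one 1-kernel conv + identity-margin dense.

    The central output's logit margin is 2 * sum(weights * patch), so the
    box optimum is sign(weights) and the per-column simplex optimum is the
    column argmax — closed forms the optimizers must match.
    """
    from zdnapred import ConvBlock, DenseBlock, ModelSpec

    n_ch, width = weights.shape
    spec = ModelSpec((ConvBlock(1, 1, width), DenseBlock(1)))
    net = model_zoo.build_network(spec, n_ch, np.random.default_rng(0))
    net.layers[0].W.value[...] = weights[None]
    net.layers[0].b.value[...] = 0.0
    net.layers[1].W.value[...] = np.array([[-1.0], [1.0]])
    net.layers[1].b.value[...] = 0.0
    return model_zoo.TrainedModel(spec, net, list(channel_names), [], 0)
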
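"""Shared fixtures: reference phantoms and (expensively) trained classifiers.

The heavy fixtures are session-scoped so one training run serves every test
that needs a fitted network.
"""

from __future__ import annotations

import numpy as np
import pytest

from somafind.candidate_detection import detect_candidates
from somafind.classifier import NetworkSpec, TrainingConfig, build_network, train
from somafind.synthetic_data import (
    PhantomSpec,
    generate_phantom,
    make_labelled_cuboid_set,
)
from somafind.volume_io import CellRecord, VoxelGeometry


@pytest.fixture(scope="session")
def geometry() -> VoxelGeometry:
    return VoxelGeometry(2.0, 2.0, 5.0)


@pytest.fixture(scope="session")
def rescue_phantom():
    """25 separated cells + 25 dual-channel blob artefacts, plus candidates."""
    spec = PhantomSpec(
        shape=(256, 256, 40),
        n_cells=25,
        n_artefacts=25,
        artefact_kinds=("bright_blob",),
        seed=21,
    )
    signal, autofluo, truth = generate_phantom(spec)
    clusters = detect_candidates(signal)
    candidates = [CellRecord(*c.centroid, label="candidate") for c in clusters]
    return spec, signal, autofluo, truth, candidates


@pytest.fixture(scope="session")
def labelled_200():
    """200 balanced labelled cuboids (100 cells, 100 artefacts)."""
    return make_labelled_cuboid_set(PhantomSpec(seed=22), 100)


@pytest.fixture(scope="session")
def trained_model(labelled_200):
    """Depth-18 network trained on the 200-cuboid set (<= 20 epochs)."""
    model = build_network(NetworkSpec(depth=18, base_width=8), seed=0)
    model, history = train(model, labelled_200, TrainingConfig(seed=0, max_epochs=20))
    return model, history


@pytest.fixture(scope="session")
def shifted_sets():
    """Labelled cuboids from a noisier acquisition (noise SD 10 -> 40)."""
    train_set = make_labelled_cuboid_set(PhantomSpec(seed=30, noise_sd=40.0), 100)
    test_set = make_labelled_cuboid_set(PhantomSpec(seed=31, noise_sd=40.0), 50)
    return train_set, test_set
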
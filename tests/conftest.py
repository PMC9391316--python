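"""Shared fixtures: synthetic datasets and trained models.

Heavy artifacts (trained networks, large KDE fits) are session-scoped so
unit, property and acceptance tests reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from particleprint import (Fingerprint, TrainConfig, plugin_bandwidth,
                           render_class, train_classifier, train_embedder)
from particleprint.synthetic import (default_study_specs, fa_panel_specs,
                                     subtle_pair_specs)


def make_split_data(specs, n_per_class, seed, splits=("train", "test"),
                    fractions=(0.8, 0.2)):
    """In-memory stratified split: {split: [ParticleImage]}."""
    rng = np.random.default_rng(seed)
    data = {s: [] for s in splits}
    for ci, spec in enumerate(specs):
        imgs = render_class(spec, n_per_class, seed=seed, class_idx=ci)
        order = rng.permutation(n_per_class)
        start = 0
        for s, f in zip(splits, fractions):
            n = int(round(f * n_per_class))
            data[s] += [imgs[i] for i in order[start:start + n]]
            start += n
    return data


@pytest.fixture(scope="session")
def four_class_data():
    return make_split_data(default_study_specs(), 500, seed=42)


@pytest.fixture(scope="session")
def four_class_model(four_class_data):
    return train_classifier(four_class_data, TrainConfig(seed=3))


@pytest.fixture(scope="session")
def six_class_data():
    return make_split_data(fa_panel_specs(), 300, seed=42)


@pytest.fixture(scope="session")
def six_class_model(six_class_data):
    return train_classifier(six_class_data, TrainConfig(seed=3))


@pytest.fixture(scope="session")
def subtle_pair_data():
    return make_split_data(subtle_pair_specs(), 2000, seed=42)


@pytest.fixture(scope="session")
def subtle_pair_model(subtle_pair_data):
    return train_classifier(subtle_pair_data, TrainConfig(seed=3))


@pytest.fixture(scope="session")
def three_class_embedder():
    specs = default_study_specs()
    specs = [specs[0], specs[1], specs[3]]
    data = make_split_data(specs, 250, seed=42, splits=("train", "val"),
                           fractions=(0.8, 0.2))
    model, log = train_embedder(data, TrainConfig(seed=3))
    return model, log, data


@pytest.fixture(scope="session")
def bimodal_fingerprint():
    """A bimodal 1000-point null fingerprint with plug-in bandwidth."""
    rng = np.random.default_rng(5)
    pts = np.vstack([rng.standard_normal((600, 2)),
                     rng.standard_normal((400, 2)) * 0.6 + np.array([3.0, 1.0])])
    return Fingerprint(points=pts, H=plugin_bandwidth(pts), label="null")


@pytest.fixture(scope="session")
def gaussian_20k_bandwidth():
    """Plug-in bandwidth of 20,000 standard bivariate normal samples."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal((20000, 2))
    return x, plugin_bandwidth(x)
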
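"""Shared fixtures: a small generated leaf dataset on disk and in memory."""

from __future__ import annotations

import numpy as np
import pytest

from lsetnet import GeneratorConfig, generate_arrays, generate_dataset


@pytest.fixture(scope="session")
def leaf_folder(tmp_path_factory):
    """A 12-class synthetic dataset written as class-per-folder PNGs."""
    root = tmp_path_factory.mktemp("leaves")
    cfg = GeneratorConfig(image_size=48, n_per_class=5, seed=7)
    manifest = generate_dataset(cfg, root)
    return root, manifest


@pytest.fixture(scope="session")
def leaf_arrays():
    """In-memory synthetic dataset: (images uint8, labels int, class names)."""
    return generate_arrays(GeneratorConfig(image_size=48, n_per_class=8, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
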
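import numpy as np
import pytest
from hypothesis import settings

import pepgraph as pg

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference():
    """The shipped reference benchmark (5 labels, n=2000, 5% dual-label)."""
    data, manifest, cfg = pg.reference_fixture()
    return data, manifest, cfg


@pytest.fixture(scope="session")
def reference_split(reference):
    data, _, _ = reference
    return pg.split_dataset(data, 0.8, seed=1)


@pytest.fixture(scope="session")
def trained_ensemble(reference, reference_split):
    """Three repeat models trained on the reference fixture at default config.

    Session-scoped because training dominates suite runtime; every test
    that needs a converged model shares these.
    """
    data, _, _ = reference
    train_set, _ = reference_split
    models = []
    for seed in (0, 1, 2):
        model = pg.build_composition_model(data.label_space, seed=seed)
        model, _ = pg.train(model, train_set,
                            pg.TrainConfig(epochs=100, n_repeats=1, seed=seed))
        models.append(model)
    return models


@pytest.fixture()
def tiny_dataset():
    """A small deterministic dataset for fast unit tests."""
    cfg = pg.SynthConfig(n_samples=80, motif_mutation_rate=0.0, seed=11,
                         length_range=(10, 25))
    data, manifest = pg.generate(cfg)
    return data, manifest
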
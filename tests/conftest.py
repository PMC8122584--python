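"""Shared fixtures: small synthetic cohorts and tiny network configs.

Everything is generated programmatically at collection time; sizes are
kept small so the whole suite runs on one CPU.
"""

import numpy as np
import pytest

from omicsfuse import SimulationSpec, simulate_multiomics
from omicsfuse.autoencoders import default_config


def tiny_config(variant: str, **overrides):
    """A shrunken EncoderConfig for fast unit tests."""
    base = dict(epochs=20, batch_size=16, seed=0)
    if variant == "variational":
        base.update(layer_widths=(32, 16), latent_dim=8)
    else:
        base.update(layer_widths=(32, 8, 32), latent_dim=8)
    base.update(overrides)
    return default_config(variant, **base)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        n_subtypes=3,
        samples_per_subtype=(20, 20, 20),
        omic_widths=(120, 100, 60),
        hazards=(0.01, 0.004, 0.001),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_multiomics(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def blob_embedding():
    """A hand-planted 3-blob embedding (60 x 10) with tight clusters."""
    rng = np.random.default_rng(42)
    centers = rng.normal(0, 5, size=(3, 10))
    labels = np.repeat(np.arange(3), 20)
    emb = centers[labels] + rng.normal(0, 0.3, size=(60, 10))
    return emb, labels
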
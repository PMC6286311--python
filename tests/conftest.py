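"""Shared fixtures: small synthetic fields and an inexpensive trained classifier.

Everything is generated at run time from seeds; nothing is loaded from disk.
The "small" study conditions shrink only the geometry (field size, colony
radii) so unit tests stay fast; the full-size default conditions are used
in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lilack.colony_sim import ColonySimParams, generate_field
from lilack.patch_cnn import TrainHyper, train_with_mining

SMALL = dict(
    field_width_px=560,
    field_height_px=420,
    n_colonies=3,
    colony_radius_um=(70.0, 130.0),
    differentiated_fraction=0.3,
)


def small_params(seed: int, **overrides) -> ColonySimParams:
    return ColonySimParams(**{**SMALL, **overrides, "seed": seed})


@pytest.fixture(scope="session")
def small_field():
    """(phase, fluor, mask, pop) of one small seeded field."""
    return generate_field(small_params(101))


@pytest.fixture(scope="session")
def small_field_holdout():
    return generate_field(small_params(202))


@pytest.fixture(scope="session")
def fast_hyper():
    return TrainHyper(epochs=4, n_patches=120, seed=7)


@pytest.fixture(scope="session")
def tiny_clf(small_field, fast_hyper):
    """Two-round-trained classifier on the small training field."""
    phase, _, mask, _ = small_field
    return train_with_mining([(phase, mask)], fast_hyper)
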
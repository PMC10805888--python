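"""Shared fixtures: small synthetic challenge bundles reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from polypeval import (
    PerturbationSpec,
    SceneSpec,
    generate_ground_truth,
    simulate_predictions,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A small 4-split ground-truth bundle (8 frames per split)."""
    spec = SceneSpec(
        split_counts={"data1": 8, "data2": 8, "data3": 8, "data4": 8},
        seed=11,
    )
    return generate_ground_truth(spec)


@pytest.fixture(scope="session")
def identity_predictions(small_fixture):
    """Predictions equal to the ground truth (zero perturbation)."""
    return simulate_predictions(small_fixture, PerturbationSpec.identity(seed=7))


@pytest.fixture(scope="session")
def noisy_predictions(small_fixture):
    """Predictions with the default moderate error model."""
    return simulate_predictions(small_fixture, PerturbationSpec(seed=13))
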
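"""Shared fixtures: synthetic warehouse datasets and small toy problems."""

from __future__ import annotations

import numpy as np
import pytest

import spoilwarn as sw


@pytest.fixture(scope="session")
def embedded_dataset():
    """One default embedded-signal study (72 x 3000), split, with truth."""
    config = sw.WarehouseSimConfig(embed_signal=True, seed=11)
    dataset, truth = sw.simulate_dataset(config)
    dataset = sw.split_calibration_prediction(dataset, 2 / 3, seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def day_labelled_dataset():
    """Default study with labels = acquisition day (no embedded signal)."""
    dataset, _ = sw.simulate_dataset(sw.WarehouseSimConfig(seed=5))
    return sw.split_calibration_prediction(dataset, 2 / 3, seed=5)


def make_toy(
    n: int = 30,
    p: int = 10,
    informative: tuple[int, ...] = (4,),
    coefficients: tuple[float, ...] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
):
    """Tiny regression problem with known informative variables (1-based)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if coefficients is None:
        coefficients = tuple(2.0 for _ in informative)
    y = np.zeros(n)
    for idx, coef in zip(informative, coefficients):
        y += coef * X[:, idx - 1]
    y += rng.normal(0.0, noise_sd, size=n)
    return X, y


@pytest.fixture(scope="session")
def toy_single_informative():
    """n=30, p=10 toy whose only signal sits in variable 4."""
    return make_toy(seed=1)
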
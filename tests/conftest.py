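"""Shared fixtures: small phantoms reused across the suite for speed."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from fibroquant import GridSpec, TissueProperties, TrajectorySpec
from fibroquant.phantom import make_label_map, simulate_echo_pair


@pytest.fixture(scope="session")
def grid48() -> GridSpec:
    return GridSpec(shape=(48, 48, 48), spacing=(1.2, 1.2, 1.2))


@pytest.fixture(scope="session")
def grid64() -> GridSpec:
    return GridSpec(shape=(64, 64, 64), spacing=(0.9, 0.9, 0.9))


@pytest.fixture(scope="session")
def props() -> TissueProperties:
    return TissueProperties()


@pytest.fixture(scope="session")
def trajectory() -> TrajectorySpec:
    return TrajectorySpec()


@pytest.fixture(scope="session")
def label_map_factory(trajectory):
    """Memoised phantom generator shared by the whole session."""

    @functools.lru_cache(maxsize=32)
    def build(shape, spacing, day, seed, control=False):
        grid = GridSpec(shape=shape, spacing=spacing)
        traj = TrajectorySpec.control() if control else trajectory
        return make_label_map(grid, traj, day, seed)

    def factory(grid: GridSpec, day: int, seed: int, control: bool = False):
        return build(grid.shape, grid.spacing, day, seed, control)

    return factory


@pytest.fixture(scope="session")
def echo_factory(props):
    cache: dict[tuple, object] = {}

    def factory(label_map, noise_sigma=0.0, seed=0):
        key = (id(label_map), noise_sigma, seed)
        if key not in cache:
            cache[key] = simulate_echo_pair(label_map, props, noise_sigma, seed)
        return cache[key]

    return factory
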
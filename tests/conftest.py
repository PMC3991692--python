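"""Shared fixtures: phantoms and pipeline outputs reused across test modules.

Everything is generated programmatically; expensive artifacts are
session-scoped so the full suite builds each of them once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lcmicro import (
    PhantomSpec,
    SegConfig,
    VoxelGrid,
    analyze_volume,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """Default study conditions on the desk-scale grid (speckle 0.3, shadows 0.1)."""
    return dataclasses.replace(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def phantom_default(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def noise_free_spec(default_spec) -> PhantomSpec:
    return dataclasses.replace(default_spec, speckle_contrast=0.0, shadow_fraction=0.0)


@pytest.fixture(scope="session")
def phantom_noise_free(noise_free_spec):
    return generate_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def speckle_spec(default_spec) -> PhantomSpec:
    """Speckle 0.3 without vessel shadows."""
    return dataclasses.replace(default_spec, shadow_fraction=0.0)


@pytest.fixture(scope="session")
def phantom_speckle(speckle_spec):
    return generate_phantom(speckle_spec)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced grid for cheap end-to-end tests."""
    return PhantomSpec(
        grid=VoxelGrid(shape=(96, 96, 72)),
        lc_depth=200.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def phantom_small(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def seg_config() -> SegConfig:
    return SegConfig()


@pytest.fixture(scope="session")
def analyzed_noise_free(phantom_noise_free, seg_config):
    """(LCParams, Segmentation) of the noise-free phantom, full pipeline."""
    return analyze_volume(phantom_noise_free.volume, seg_config)


@pytest.fixture(scope="session")
def analyzed_speckle(phantom_speckle, seg_config):
    """(LCParams, Segmentation) of the speckle-0.3 phantom, full pipeline."""
    return analyze_volume(phantom_speckle.volume, seg_config)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    s = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / s if s else 1.0
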
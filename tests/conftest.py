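"""Shared fixtures: small synthetic configurations for fast tests."""

import numpy as np
import pytest

from serofir.simulate import SimConfig, default_bands, preset


@pytest.fixture
def small_config() -> SimConfig:
    """A shrunk design (coarser grid, few subjects) for fast unit tests."""
    return SimConfig(
        grid_step=3.0,
        n_subjects_per_class=4,
        n_replicates_per_subject=5,
        seed=11,
    )


@pytest.fixture
def clean_config() -> SimConfig:
    """Small design with every measurement artifact switched off."""
    return SimConfig(
        grid_step=3.0,
        n_subjects_per_class=3,
        n_replicates_per_subject=2,
        subject_sd=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        baseline_sd=0.0,
        noise_sd=0.0,
        water_vapor_amplitude=0.0,
        seed=5,
    )


@pytest.fixture
def high_separation_config() -> SimConfig:
    """Well-separated classes on a coarse grid: a quick CNN benchmark."""
    return SimConfig(
        grid_step=3.0,
        n_subjects_per_class=6,
        n_replicates_per_subject=6,
        bands=tuple(default_bands("high")),
        subject_sd=0.05,
        seed=21,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
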
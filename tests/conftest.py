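"""Shared fixtures: toy frames, speckle scenes, and the synthetic cohort."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from slscbf.rf_data import AcquisitionGeometry, ChannelDataFrame
from slscbf.simulator import DESK_GEOMETRY, SceneConfig, make_cohort, simulate_scene


def make_toy_frame(
    n_samples: int = 16,
    n_elements: int = 6,
    n_lines: int = 4,
    seed: int = 0,
    polarity_tag: str = "fundamental",
) -> ChannelDataFrame:
    """Small random frame for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    geometry = AcquisitionGeometry(n_receive_elements=n_elements, n_scan_lines=n_lines)
    samples = rng.standard_normal((n_samples, n_elements, n_lines))
    return ChannelDataFrame(samples, geometry, polarity_tag, delays_applied=True)


@pytest.fixture
def toy_frame() -> ChannelDataFrame:
    return make_toy_frame()


@pytest.fixture(scope="session")
def speckle_geometry() -> AcquisitionGeometry:
    """Few-line desk geometry for speckle physics checks."""
    return dataclasses.replace(DESK_GEOMETRY, n_scan_lines=24)


@pytest.fixture(scope="session")
def speckle_pair(speckle_geometry):
    """Tissue-only scene: diffuse speckle, no clutter, no distortion."""
    config = SceneConfig(
        mass_kind=None, clutter_level_db=None, harmonic_distortion=0.0, seed=3
    )
    return config, simulate_scene(config, speckle_geometry)


@pytest.fixture(scope="session")
def cohort_7_28():
    """The 7-fluid / 28-solid synthetic cohort used in end-to-end checks."""
    return make_cohort(7, 28, seed=20240109)
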
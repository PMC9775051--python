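"""Shared fixtures: one synthetic study-condition dataset reused across tests."""

import numpy as np
import pytest

from tdfshift import GroundTruth, generate_dataset
from tdfshift.decay import DecayCurve


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    """Study-condition ground truth (fluid bilayer, 15 wavelengths)."""
    return GroundTruth(seed=0)


@pytest.fixture(scope="session")
def dataset(truth):
    return generate_dataset(truth)


@pytest.fixture(scope="session")
def noiseless_decays(truth, dataset):
    """The Poisson-free measured decays (IRF-convolved expectations)."""
    return [
        DecayCurve(counts=c, channel_width=truth.channel_width, wavelength=w)
        for c, w in zip(dataset.noiseless_decays, truth.wavelengths)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
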
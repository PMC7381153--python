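"""Shared fixtures: small grids and simulated subjects for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from favint import AcquisitionSpec, generate_block_sequence
from favint.synth import GroundTruth, make_integration_truth, n_scans_for


@pytest.fixture(scope="session")
def integration_seq():
    return generate_block_sequence("integration", seed=11)


@pytest.fixture(scope="session")
def small_spec(integration_seq):
    """Compact grid covering part of the right temporal slab."""
    return AcquisitionSpec(
        tr=2.0,
        n_scans=n_scans_for(integration_seq, 2.0),
        grid_shape=(10, 12, 10),
        smooth_fwhm_mm=8.0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(small_spec):
    truth = make_integration_truth(small_spec, "SAD", seed=21)
    truth.innovation_sd = 0.0
    truth.drift_amplitude = 0.0
    return truth


def quiet_truth(spec, group="SAD", seed=0, **kw):
    """Helper: truth with small configurable noise."""
    truth = make_integration_truth(spec, group, seed=seed, **kw)
    return truth
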
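import numpy as np
import pytest

from lcfp import (
    DirectionSet,
    PopulationSpec,
    ReconConfig,
    estimate_z0,
    simulate_signals,
)
from lcfp.phantom import make_scheme, make_template


@pytest.fixture(scope="session")
def dirs321():
    return DirectionSet.default()


@pytest.fixture(scope="session")
def scheme64():
    return make_scheme(64, 2000.0, 1)


@pytest.fixture(scope="session")
def tiny_phantom():
    """One noiseless scan on a 5x5x5 crossing-slab grid, with ground truth."""
    spec = PopulationSpec(
        seed=11, n_subjects=1, sessions_per_subject=1, grid_shape=(5, 5, 5), noise="none"
    )
    scans, truth = simulate_signals(spec)
    return scans[0], truth


@pytest.fixture(scope="session")
def tiny_cfg(tiny_phantom, dirs321):
    scan, _ = tiny_phantom
    cfg = ReconConfig()
    z0 = estimate_z0(scan.dwi, cfg, dirs321)
    return ReconConfig(z0=z0)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 sessions at the calibrated default noise level."""
    spec = PopulationSpec(seed=7, n_subjects=10, sessions_per_subject=2, keep_noiseless=False)
    return simulate_signals(spec)


@pytest.fixture(scope="session")
def template12():
    return make_template((12, 12, 8), "crossing-slab")
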
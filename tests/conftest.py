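import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from qsmcl import (KineticsConfig, RegionMask, gen_origami_grid,
                   simulate_imaging, simulate_kinetics)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def roi_5um():
    return RegionMask.rectangle(5_000.0, 5_000.0)


@pytest.fixture
def roi_10um():
    return RegionMask.rectangle(10_000.0, 10_000.0)


@pytest.fixture(scope="session")
def nnd_kinetics():
    """Acquisition settings of an NND-style run (80k frames, 100 ms)."""
    return KineticsConfig(n_frames=80_000)


@pytest.fixture(scope="session")
def qpaint_kinetics():
    """Acquisition settings of a qPAINT-style run (160k frames, 100 ms)."""
    return KineticsConfig(n_frames=160_000)


@pytest.fixture(scope="session")
def sparse_sites_table(nnd_kinetics):
    """25 well-separated single docking sites imaged over 80k frames."""
    layout = gen_origami_grid(5, 5, spacing_nm=2_000.0)
    table, traces = simulate_imaging(layout, nnd_kinetics, seed=101)
    return layout, table, traces


@pytest.fixture(scope="session")
def reference_single_site_traces(qpaint_kinetics):
    """200 single-site reference traces for qPAINT influx calibration."""
    layout = gen_origami_grid(10, 20, spacing_nm=2_000.0)
    return simulate_kinetics(layout, qpaint_kinetics, seed=202)
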
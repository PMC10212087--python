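"""Shared fixtures: session-scoped synthetic runs reused across test modules."""

import numpy as np
import pytest

from spheromech import presets
from spheromech.pipeline import analyze_compression, analyze_tem_strip
from spheromech.synth_mech import simulate_compression_experiment
from spheromech.synth_tem import sample_cell_tessellation, render_tem_panels


@pytest.fixture(scope="session")
def day20_compression():
    """One noiseless day-20 compression experiment with ground truth."""
    return simulate_compression_experiment(
        presets.ACTUATION, presets.CANTILEVER, presets.DAY20_SPHEROID,
        noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def day20_result_noisy():
    """Full day-20 pipeline result at 2% pixel noise."""
    return analyze_compression(presets.DAY20_SPHEROID, seed=5, noise_sd=0.02)


@pytest.fixture(scope="session")
def day5_strip():
    """A reduced day-5 tessellation strip (300x60 μm) with its panels."""
    strip = sample_cell_tessellation(300.0, 60.0, presets.TEM_PRESETS["day5"], seed=3)
    panels, cells_per_panel = render_tem_panels(strip, render=False)
    return strip, panels, cells_per_panel


@pytest.fixture(scope="session")
def day20_strip_full():
    """One full-size day-20 strip analyzed end to end."""
    return analyze_tem_strip(presets.TEM_PRESETS["day20"],
                             presets.DAY20_SPHEROID.diameter_um,
                             seed=2, group="day20")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
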
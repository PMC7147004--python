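import numpy as np
import pytest

from lungclock import simulate
from lungclock.io import ExposureGroup


@pytest.fixture(scope="session")
def preset():
    """The default multi-study scenario, generated once per session."""
    return simulate.scenario_three_study(1)


@pytest.fixture(scope="session")
def preset_sham(preset):
    _, records, _ = preset
    return [r for r in records if r.exposure_group == ExposureGroup.SHAM]


@pytest.fixture(scope="session")
def sham_clock(preset, preset_sham):
    """Clock fitted on all preset sham samples."""
    from lungclock.clock import fit_clock

    matrix, _, _ = preset
    return fit_clock(matrix, preset_sham, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
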
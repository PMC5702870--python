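import numpy as np
import pytest

from numpref import (
    build_default_design,
    build_timecourses,
    default_configurations,
    feature_timecourses,
)
from numpref.features import analytic_timecourses


@pytest.fixture(scope="session")
def design():
    return build_default_design(cycles=1)


@pytest.fixture(scope="session")
def configs():
    return default_configurations()


@pytest.fixture(scope="session")
def one_cycle_tracks(design, configs):
    """Randomized feature tracks for all five regimes, one design cycle."""
    rng = np.random.default_rng(11)
    return {
        name: feature_timecourses(design, cfg, seed=int(rng.integers(2**31 - 1)))
        for name, cfg in configs.items()
    }


@pytest.fixture(scope="session")
def analytic_tracks(design, configs):
    """Placement-independent tracks (item geometry + display RMS contrast)."""
    return {name: analytic_timecourses(design, cfg) for name, cfg in configs.items()}
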
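"""Shared fixtures: expensive network runs are computed once per session."""

import numpy as np
import pytest

import mtpattern as mp
from mtpattern.experiments import (COMPONENT_EXEMPLAR, PATTERN_EXEMPLAR,
                                   run_gain_sweep, run_timecourse,
                                   run_v1_maps)

GRID3 = (0.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def config():
    return mp.default_config()


@pytest.fixture(scope="session")
def crossing_maps():
    """V1 population maps and terminator statistics, crossing-bar preset."""
    return run_v1_maps("crossing")


@pytest.fixture(scope="session")
def pattern_maps():
    """V1 maps for the occluded-terminator (pattern) preset."""
    return run_v1_maps("pattern")


@pytest.fixture(scope="session")
def pattern_timecourse():
    """Full network run at the pattern-regime exemplar gains, with probe."""
    return run_timecourse(PATTERN_EXEMPLAR)


@pytest.fixture(scope="session")
def component_timecourse():
    """Full network run at the component-regime exemplar gains, with probe."""
    return run_timecourse(COMPONENT_EXEMPLAR)


@pytest.fixture(scope="session")
def gain_sweep():
    """3x3 pattern-index sweep on the equal-contrast pattern stimulus."""
    return run_gain_sweep(GRID3, GRID3)


@pytest.fixture(scope="session")
def contrast_sweep():
    """3x3 sweep with unequal bar contrasts (1.0, 0.5)."""
    return run_gain_sweep(GRID3, GRID3, contrasts=(1.0, 0.5))
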
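import numpy as np
import pytest

from eitbladder.datasets import IdealFrameSimulator, build_testcase, tc_spec
from eitbladder.forward import assign_conductivity, forward_solve, make_stim_pattern
from eitbladder.geometry import (MeshDensity, PelvisBoundary, RadiiModel,
                                 bladder_radii_from_volume, build_pelvis_mesh,
                                 place_bladder)


@pytest.fixture(scope="session")
def radii_model():
    return RadiiModel()


@pytest.fixture(scope="session")
def male_pelvis():
    return PelvisBoundary.standard("male")


@pytest.fixture(scope="session")
def bladder240(radii_model, male_pelvis):
    return place_bladder(bladder_radii_from_volume(240.0, radii_model),
                         male_pelvis, radii_model, volume_ml=240.0)


@pytest.fixture(scope="session")
def mesh240(male_pelvis, bladder240):
    return build_pelvis_mesh(male_pelvis, bladder240)


@pytest.fixture(scope="session")
def pattern32():
    return make_stim_pattern(32, 4, 5.0)


@pytest.fixture(scope="session")
def frame240(mesh240, pattern32):
    return forward_solve(mesh240, assign_conductivity(mesh240, 0.2, 1.75), pattern32)


@pytest.fixture(scope="session")
def sim2d():
    """Shared 2-D simulator cache for dataset-level tests."""
    return IdealFrameSimulator(domain="2d")


@pytest.fixture(scope="session")
def tc1_tiny(sim2d):
    """TC1 grid with a small replicate count, for fast pipeline tests."""
    spec = tc_spec(1, n_noisy=4)
    return build_testcase(spec, 60.0, seed=123, simulator=sim2d)
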
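import numpy as np
import pytest

from pet4d import (FrameSchedule, PhantomSpec, ScanGeometry, make_basis_set,
                   make_input_function, make_population,
                   simulate_dynamic_counts)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def cp():
    return make_input_function()


@pytest.fixture(scope="session")
def basis_small(cp, schedule):
    """50-basis set over the default k2 range (fast, coarse grid)."""
    return make_basis_set(cp, schedule, n_bases=50)


@pytest.fixture(scope="session")
def basis_200(cp, schedule):
    return make_basis_set(cp, schedule, n_bases=200)


@pytest.fixture(scope="session")
def tiny_geometry():
    return ScanGeometry(n_angles=60, n_bins=49)


@pytest.fixture(scope="session")
def tiny_subject():
    spec = PhantomSpec(grid_size=32, n_subjects=2, between_subject_cv=0.1)
    return make_population(spec, seed=7)[0]


@pytest.fixture(scope="session")
def tiny_stack(tiny_subject, cp, schedule, tiny_geometry):
    return simulate_dynamic_counts(tiny_subject, cp, schedule, tiny_geometry,
                                   seed=11)
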
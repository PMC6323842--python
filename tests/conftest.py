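import numpy as np
import pytest

from breath4d import dose, evaluate as ev, phantom


@pytest.fixture(scope="session")
def small_grid():
    """A reduced grid (transverse 44 mm, full SI extent) that still fits
    the 3-cm sphere with its penumbra; keeps dose builds fast."""
    return phantom.PhantomGrid(shape=(44, 44, 120))


@pytest.fixture(scope="session")
def default_spec():
    return dose.PlanSpec()


@pytest.fixture(scope="session")
def gtv3(small_grid):
    return phantom.make_gtv_mask(small_grid, phantom.TargetGeometry(3.0, 0))


@pytest.fixture(scope="session")
def plan15(small_grid, default_spec):
    """Traditional plan for a 15-mm homogeneous planning curve, 3-cm target."""
    positions = ev.traditional_phase_positions(15.0)
    itv = phantom.build_itv(small_grid, 3.0, positions)
    return dose.plan_dose(itv, default_spec)


@pytest.fixture(scope="session")
def sampler15(plan15, gtv3):
    return ev.ShiftDoseSampler(plan15, gtv3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
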
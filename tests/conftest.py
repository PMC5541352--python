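import numpy as np
import pytest

from pyfelix import (FrustumAccumulator, UnitCell, get_scenario,
                     simulate_image)


@pytest.fixture(scope="session")
def rho_g6():
    return get_scenario("rho-g6")


@pytest.fixture(scope="session")
def lysozyme():
    return get_scenario("lysozyme")


@pytest.fixture(scope="session")
def at1r():
    return get_scenario("at1r")


@pytest.fixture(scope="session")
def toy_cubic():
    """A small cubic cell for exhaustive brute-force oracles."""
    return UnitCell(1.0, 1.0, 1.0, laue_class="m-3m")


@pytest.fixture(scope="session")
def warm_tracer():
    """Compile the numba kernels once on a tiny problem."""
    acc = FrustumAccumulator(8)
    acc.trace_pairs(np.array([[0.0, 1.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]))
    return True


@pytest.fixture(scope="session")
def lysozyme_single_image(lysozyme):
    """One noise-free single-crystal lysozyme snapshot (fixed seed)."""
    rng = np.random.default_rng(42)
    return simulate_image(1, lysozyme, rng)
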
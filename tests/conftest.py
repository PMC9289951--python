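import numpy as np
import pytest

import ktnfpt as kf


@pytest.fixture
def two_state():
    """Two equal minima, one barrier of 2: rate e^-2 each way at T=1."""
    ktn = kf.KTN(
        [kf.Minimum(1, 0.0), kf.Minimum(2, 0.0)],
        [kf.TransitionState(1, 2.0, 1, 2)],
    )
    return ktn


@pytest.fixture
def two_state_k2():
    """Absorbing two-state problem with escape rate k = 2 at T = 1.

    The rate prefactor of 2 comes from the minima's frequency product
    (entropic), since a barrier can only reduce a rate below 1.
    """
    lfp = np.log(2.0)
    ktn = kf.KTN(
        [kf.Minimum(1, 0.0, lfp), kf.Minimum(2, 0.0, lfp)],
        [kf.TransitionState(1, 0.0, 1, 2)],
    )
    rm = kf.build_rate_model(ktn, 1.0)
    return kf.AbsorbingProblem(rm, A={2}, B={1})


@pytest.fixture
def three_chain():
    """Linear chain 1-2-3 with all rates 1 (zero barriers at T=1)."""
    ktn = kf.KTN(
        [kf.Minimum(i, 0.0) for i in (1, 2, 3)],
        [kf.TransitionState(1, 0.0, 1, 2), kf.TransitionState(2, 0.0, 2, 3)],
    )
    return ktn


@pytest.fixture
def three_chain_problem(three_chain):
    rm = kf.build_rate_model(three_chain, 1.0)
    return kf.AbsorbingProblem(rm, A={3}, B={1})


@pytest.fixture(scope="session")
def fixture_landscape():
    return kf.generate_multifunnel(kf.DEFAULT_LANDSCAPE)


@pytest.fixture(scope="session")
def fixture_problem_T2(fixture_landscape):
    spec = kf.DEFAULT_LANDSCAPE
    rm = kf.build_rate_model(fixture_landscape, 2.0)
    return kf.AbsorbingProblem(rm, A={spec.product}, B={spec.reactant})


@pytest.fixture(scope="session")
def fixture_problem_T1(fixture_landscape):
    spec = kf.DEFAULT_LANDSCAPE
    rm = kf.build_rate_model(fixture_landscape, 1.0)
    return kf.AbsorbingProblem(rm, A={spec.product}, B={spec.reactant})


@pytest.fixture(scope="session")
def fixture_spectral_T2(fixture_problem_T2):
    return kf.spectral_decompose(fixture_problem_T2)


@pytest.fixture(scope="session")
def fixture_spectral_T1(fixture_problem_T1):
    return kf.spectral_decompose(fixture_problem_T1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
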
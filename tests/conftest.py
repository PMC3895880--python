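import numpy as np
import pytest

import eigenlocal as el
from eigenlocal.network_models import (
    GradientRangeParams,
    GradientSelfCouplingParams,
    RandomSelfCouplingParams,
)

# Published caption parameters, reused across the suite.
FIG3_STRONG = dict(mu0=-1.9, delta_r=0.01, mu_f=0.2, mu_b=0.1, l_c=4.0)
FIG3_WEAK = dict(mu0=-1.9, delta_r=0.0015, mu_f=0.2, mu_b=0.1, l_c=4.0)
FIG5 = dict(mu0=-1.05, mu_f=5.0, mu_b=0.5, f0=0.2, f1=0.12, b0=6.0,
            b1=0.11, noise_sd=1e-5)
FIG6 = dict(mu0=-1.0, mu_c=0.05, l_c=4.0)


@pytest.fixture(scope="session")
def ring100():
    return el.build_ring(100, 1.0)


@pytest.fixture(scope="session")
def ring100_dec(ring100):
    return el.decompose(ring100)


@pytest.fixture(scope="session")
def fig3_strong_net():
    return el.build_gradient_self_coupling(
        100, GradientSelfCouplingParams(**FIG3_STRONG))


@pytest.fixture(scope="session")
def fig3_strong_dec(fig3_strong_net):
    return el.decompose(fig3_strong_net)


@pytest.fixture(scope="session")
def fig3_weak_net():
    return el.build_gradient_self_coupling(
        100, GradientSelfCouplingParams(**FIG3_WEAK))


@pytest.fixture(scope="session")
def fig3_weak_dec(fig3_weak_net):
    return el.decompose(fig3_weak_net)


@pytest.fixture(scope="session")
def fig5_net():
    return el.build_gradient_range(50, GradientRangeParams(seed=0, **FIG5))


@pytest.fixture(scope="session")
def fig5_dec(fig5_net):
    return el.decompose(fig5_net, tol=1e-6)


@pytest.fixture(scope="session")
def fig6_net():
    return el.build_random_self_coupling(
        100, RandomSelfCouplingParams(sigma=0.33, seed=0, **FIG6))


@pytest.fixture(scope="session")
def fig6_dec(fig6_net):
    return el.decompose(fig6_net)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
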
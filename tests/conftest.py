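import numpy as np
import pytest

from dnacondense import SolventCondition, make_chain


@pytest.fixture(scope="session")
def chain_200bp():
    return make_chain(200)


@pytest.fixture(scope="session")
def chain_2500bp():
    return make_chain(2500)


@pytest.fixture(scope="session")
def chain_lambda():
    """Phage lambda DNA, 48.5 kb."""
    return make_chain(48500)


@pytest.fixture(scope="session")
def poor_solvent():
    return SolventCondition(chi=0.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def grid_search_alpha(chain, solvent, alpha_max=1.5, step=1e-4):
    """Independent oracle: dense grid minimization of the internal free energy.

    Written directly against the closed-form expression (not through the
    package's internal_free_energy) so the solver and the oracle share no
    code path.
    """
    n, w = chain.segment_number_N, chain.omega
    chi, b2, b3 = solvent.chi, solvent.B2, solvent.B3
    a = np.arange(step, alpha_max + step / 2, step)
    g = (
        n * ((chi - 1.0) + b2 * w / (2.0**1.5 * a**3) + b3 * w**2 / (2.0 * 3.0**2.5 * a**6))
        + 1.5 * (a**2 - 1.0)
        - 3.0 * np.log(a)
    )
    return float(a[np.argmin(g)])
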
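import numpy as np
import pytest

from uelomax import UELParams

# the six parameter triples used throughout the distributional tables,
# keyed as (delta, lam, theta)
CASES = {
    "a": UELParams(1.5, 0.5, 0.5),
    "b": UELParams(1.5, 0.5, 1.5),
    "c": UELParams(0.5, 0.5, 1.5),
    "d": UELParams(1.5, 2.0, 0.5),
    "e": UELParams(1.5, 2.0, 1.5),
    "f": UELParams(0.5, 2.0, 1.5),
}


@pytest.fixture(scope="session")
def cases():
    return CASES


@pytest.fixture(scope="session")
def covid():
    from uelomax import covid_fixture

    return covid_fixture()


@pytest.fixture(scope="session")
def covid_mle(covid):
    from uelomax import fit_mle

    return fit_mle(covid.values)
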
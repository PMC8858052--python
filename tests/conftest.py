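import numpy as np
import pytest

from cfcancer import ModelParameters, baseline_fixture


@pytest.fixture(scope="session")
def baseline():
    """The assumed baseline run configuration."""
    return baseline_fixture()


@pytest.fixture(scope="session")
def base_params(baseline):
    return baseline.params


@pytest.fixture(scope="session")
def base_y0(baseline):
    return baseline.y0.as_array()


@pytest.fixture(scope="session")
def hand_params():
    """Hand-solvable chain: recruitment only into stage 1-2, A->B->death.

    Equilibrium (1, 1, 0, 0, 0) by back-substitution: C_A* = eta1/delta_AB,
    C_B* = delta_AB C_A*/gamma2.
    """
    return ModelParameters(
        eta1=1.0, eta2=0.0, eta3=0.0,
        delta_AB=1.0, delta_AD=0.0, delta_BC=0.0, delta_BD=0.0, delta_BE=0.0,
        delta_CD=0.0, delta_CE=0.0, delta_DB=0.0, delta_DC=0.0, delta_DE=1.0,
        gamma1=1.0, gamma2=1.0, gamma3=1.0,
    )


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    """Random nonnegative rate draw with O(1) magnitudes."""
    from cfcancer.model import PARAM_NAMES

    vals = rng.uniform(0.01, 1.0, size=len(PARAM_NAMES))
    return ModelParameters(**dict(zip(PARAM_NAMES, vals)))
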
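import pytest

from microswitch.model import ModelParams, background_drive
from microswitch.synthetic import MotifSpec, fixture_matrix, generate_matrix


@pytest.fixture(scope="session")
def fixture_C():
    """The committed calibrated surrogate connectivity matrix."""
    return fixture_matrix()


@pytest.fixture()
def params():
    return ModelParams()


@pytest.fixture()
def base_stim():
    return background_drive(5.0)


@pytest.fixture(scope="session")
def random_matrices():
    """A bag of structurally valid surrogate matrices with varied seeds."""
    return [generate_matrix(MotifSpec(seed=s)) for s in range(10)]


def toy_raw_tables():
    """Raw tables with three active morphological types, hand-checkable."""
    import pandas as pd

    from microswitch.connectivity import MORPHOLOGICAL_TYPES

    morphs = list(MORPHOLOGICAL_TYPES)
    prob = pd.DataFrame(0.0, index=morphs, columns=morphs)
    amp = pd.DataFrame(0.0, index=morphs, columns=morphs)
    # pyramidal -> two PV subtypes
    prob.loc["basket_sup", "pyramidal_sup"] = 0.5
    amp.loc["basket_sup", "pyramidal_sup"] = 1.2
    prob.loc["chandelier_sup", "pyramidal_sup"] = 0.25
    amp.loc["chandelier_sup", "pyramidal_sup"] = 0.8
    # two PV subtypes -> pyramidal
    prob.loc["pyramidal_sup", "basket_sup"] = 0.5
    amp.loc["pyramidal_sup", "basket_sup"] = -0.8
    prob.loc["pyramidal_sup", "chandelier_sup"] = 0.4
    amp.loc["pyramidal_sup", "chandelier_sup"] = -0.5
    prevalence = pd.Series({
        "PV_sup": 0.5, "SST_sup": 1.0, "VIP_sup": 1.0,
        "PV_deep": 1.0, "SST_deep": 1.0, "VIP_deep": 1.0,
    })
    return prob, amp, prevalence
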
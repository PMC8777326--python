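import numpy as np
import pytest

import voikit as vk


@pytest.fixture(scope="session")
def depression():
    return vk.depression_model()


@pytest.fixture(scope="session")
def toy_spec():
    return vk.ToyModelSpec(mu_x=0.0, sigma_x=1.0, sigma_y=1.0)


@pytest.fixture(scope="session")
def toy(toy_spec):
    return vk.toy_model(toy_spec)


@pytest.fixture(scope="session")
def toy_truth(toy_spec):
    """(EVPI, EVPPI_X) closed-form values for the default toy model."""
    return vk.toy_closed_form(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def identical_decision_problem():
    """Two decisions with the same net benefit: every information value is 0."""
    base = vk.toy_model()

    def nb(theta):
        v = np.asarray(theta)[..., 0] + np.asarray(theta)[..., 1]
        return np.stack([v, v], axis=-1)

    return vk.DecisionProblem(
        decisions=(1, 2),
        net_benefits=nb,
        params=base.params,
        wtp=0.0,
        subsets=dict(base.subsets),
        name="identical",
    )


@pytest.fixture()
def identical_problem():
    return identical_decision_problem()
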
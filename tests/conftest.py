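import pytest

from stingmdp import PredationMDP, RewardSpec, value_iteration


@pytest.fixture(scope="session")
def mdp_cos():
    return PredationMDP(reward=RewardSpec(form="cos_example"))


@pytest.fixture(scope="session")
def mdp_atan():
    return PredationMDP(reward=RewardSpec(form="atan_example"))


@pytest.fixture(scope="session")
def vi_cos(mdp_cos):
    return value_iteration(mdp_cos)


@pytest.fixture(scope="session")
def vi_atan(mdp_atan):
    return value_iteration(mdp_atan)
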
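import pytest

from dcpcea import StrategyEvaluator, load_builtin


@pytest.fixture(scope="session")
def dmmr_scenario():
    return load_builtin("dmmr")


@pytest.fixture(scope="session")
def pmmr_scenario():
    return load_builtin("pmmr")


@pytest.fixture(scope="session")
def dmmr_eval(dmmr_scenario):
    return StrategyEvaluator(dmmr_scenario)


@pytest.fixture(scope="session")
def pmmr_eval(pmmr_scenario):
    return StrategyEvaluator(pmmr_scenario)
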
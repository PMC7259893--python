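import pytest

from paleotherm.config import build_physiology, build_scenario
from paleotherm.morphometry import build_animal


@pytest.fixture(scope="session")
def plateosaurus():
    return build_animal("plateosaurus")


@pytest.fixture(scope="session")
def coelophysis_bare():
    return build_animal("coelophysis", insulation="none")


@pytest.fixture(scope="session")
def coelophysis_full():
    return build_animal("coelophysis", insulation="full")


@pytest.fixture(scope="session")
def plateo_ratite_narrow():
    return build_physiology("ratite", "narrow", 850, taxon="plateosaurus")


@pytest.fixture(scope="session")
def hot_arid():
    return build_scenario("hot_arid")
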
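import pytest

from squadron import (
    ACTIVATION,
    INHIBITION,
    Edge,
    NetworkModel,
    Node,
    NodeCategory,
    load_crc_hroc87,
    load_treatment_scenarios,
)


@pytest.fixture(scope="session")
def crc_model() -> NetworkModel:
    return load_crc_hroc87()


@pytest.fixture(scope="session")
def treatment_scenarios():
    return {sc.name: sc for sc in load_treatment_scenarios()}


@pytest.fixture
def mutual_inhibition() -> NetworkModel:
    """Classic bistable toggle: A -| B, B -| A."""
    return NetworkModel(
        [Node("A"), Node("B")],
        [Edge("A", "B", INHIBITION), Edge("B", "A", INHIBITION)],
    )


@pytest.fixture
def chain() -> NetworkModel:
    """A -> B."""
    return NetworkModel([Node("A"), Node("B")], [Edge("A", "B", ACTIVATION)])


@pytest.fixture
def toy_phenotype_model() -> NetworkModel:
    """A drives apoptosis and suppresses proliferation; B is inert."""
    return NetworkModel(
        [
            Node("A"),
            Node("B"),
            Node("apoptosis", NodeCategory.PHENOTYPE),
            Node("proliferation", NodeCategory.PHENOTYPE),
        ],
        [
            Edge("A", "apoptosis", ACTIVATION),
            Edge("A", "proliferation", INHIBITION),
        ],
    )
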
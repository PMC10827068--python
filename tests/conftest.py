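import pytest

from hillnet import ProtocolStep, SimulationProtocol, build_cardiacdevnet, build_examplenet


@pytest.fixture
def examplenet():
    return build_examplenet()


@pytest.fixture
def cardiacdevnet():
    return build_cardiacdevnet()


@pytest.fixture
def tutorial_protocol():
    """The six-segment stimulate/washout walkthrough on the A-E network:
    all off / A on / A off / B on / B off / A and B on, 10 tau each."""
    return SimulationProtocol(
        (
            ProtocolStep(10),
            ProtocolStep(10, {"r1": 1.0}),
            ProtocolStep(10, {"r1": 0.0}),
            ProtocolStep(10, {"r2": 1.0}),
            ProtocolStep(10, {"r2": 0.0}),
            ProtocolStep(10, {"r1": 1.0, "r2": 1.0}),
        )
    )


@pytest.fixture
def cardiac_protocol():
    """Quiescent 2 tau, then GATA6 input on for 8 tau."""
    return SimulationProtocol((ProtocolStep(2), ProtocolStep(8, {"r1": 1.0})))
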
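import pytest

from umsched import AnchorSet, PatientProfile, worked_example_kb


@pytest.fixture(scope="session")
def kb():
    return worked_example_kb()


@pytest.fixture()
def default_anchors():
    return AnchorSet()


@pytest.fixture()
def default_profile():
    return PatientProfile()
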
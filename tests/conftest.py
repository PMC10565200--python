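import pytest

from graftcea.synthetic_data import make_base_case, make_lifetable


@pytest.fixture(scope="session")
def lifetable():
    return make_lifetable()


@pytest.fixture(scope="session")
def base_bundle():
    return make_base_case()
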
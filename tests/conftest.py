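import logging

import pytest

from foldsense import synthetic_data as sd

# the deliberate grid-extension notices are noise in test output
logging.getLogger("foldsense.synthetic_data").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfp():
    return sd.mcfp()


@pytest.fixture(scope="session")
def citrine():
    return sd.mcitrine()


@pytest.fixture(scope="session")
def tfp1():
    return sd.mtfp1()


@pytest.fixture(scope="session")
def venus():
    return sd.mcpvenus()
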
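import pytest

from acsmarkov import base_case, run_model


@pytest.fixture(scope="session")
def base_params():
    return base_case()


@pytest.fixture(scope="session")
def base_results(base_params):
    return run_model(base_params)
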
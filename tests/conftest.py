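import pytest

from rapeseed_fspm.parameters import ParameterStore, load_default_store


@pytest.fixture(scope="session")
def store() -> ParameterStore:
    return load_default_store()
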
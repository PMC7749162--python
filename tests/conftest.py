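import pytest

from trialaudit import bundled_lexicon_path, load_lexicons, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons(bundled_lexicon_path())
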
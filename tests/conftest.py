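import pytest

from sortanaph.fixtures import build_example_corpus, build_fixture_kb


@pytest.fixture(scope="session")
def kb():
    return build_fixture_kb()


@pytest.fixture(scope="session")
def corpus():
    return build_example_corpus()
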
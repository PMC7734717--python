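import pytest

from coofoqus import fixtures as fx
from coofoqus.kb_model import load_ontology


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    fx.write_fixture_set(out, seed=1)
    return out


@pytest.fixture(scope="session")
def dialogue_kb(fixture_dir):
    return load_ontology(fixture_dir / "dialogue.ttl")


@pytest.fixture(scope="session")
def toy_kb(fixture_dir):
    return load_ontology(fixture_dir / "toy_kb.ttl")


@pytest.fixture(scope="session")
def lexicon():
    return fx.toy_lexicon()


@pytest.fixture(scope="session")
def embeddings():
    return fx.toy_embeddings()


@pytest.fixture(scope="session")
def sessions():
    return fx.scripted_sessions()


@pytest.fixture()
def start_iri():
    return fx.DIALOGUE_NS + "utterance_health_info_776"
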
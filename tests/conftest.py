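import pytest
from hypothesis import settings

import adetag as a

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def resources():
    return a.default_resources()


@pytest.fixture(scope="session")
def lexicon(resources):
    return resources.lexicon


@pytest.fixture(scope="session")
def small_corpus():
    """A 12-document noise-free corpus (fast, fully separable)."""
    docs, gold, ledger = a.generate(
        a.GeneratorConfig(n_docs=12, seed=7, punct_attach_rate=0.0,
                          singleton_rate=0.0)
    )
    return docs, gold, ledger


@pytest.fixture(scope="session")
def noisy_corpus():
    """A 20-document corpus with default noise settings."""
    docs, gold, ledger = a.generate(a.GeneratorConfig(n_docs=20, seed=3))
    return docs, gold, ledger


def make_doc(text: str, doc_id: str = "d0") -> a.Document:
    return a.Document(doc_id, text)
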
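import pytest

from rxneval.schema import LabelSchema
from rxneval.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def schema() -> LabelSchema:
    return LabelSchema.default()


@pytest.fixture(scope="session")
def small_corpus(schema):
    """A 20-snippet fixture corpus with default study conditions."""
    return generate(GeneratorConfig(seed=11, n_snippets=20))


def make_snippet_pair(text, ann):
    """Convenience for hand-written standoff fixtures in tests."""
    return text, ann
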
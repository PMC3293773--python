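import pytest

from ontoseek.fixtures import (FixtureSpec, gen_corpus, gen_expression,
                               gen_genome, gen_ontology)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def ontology(spec):
    graph, _, _ = gen_ontology(spec)
    return graph


@pytest.fixture(scope="session")
def corpus(spec, ontology):
    docs, manifest, truth = gen_corpus(spec, ontology)
    return docs, manifest, truth


@pytest.fixture(scope="session")
def genome_fixture(spec):
    return gen_genome(spec)


@pytest.fixture(scope="session")
def expression_fixture(spec):
    return gen_expression(spec)
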
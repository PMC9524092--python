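import pytest

from headache_nlp import (
    GeneratorConfig,
    generate_corpus,
    generate_lexicon_fixtures,
    default_blocklist,
    default_stopwords,
    tokenize_corpus,
    preprocess_corpus,
    extract_theme_subcorpus,
)
from headache_nlp.sentiment import LexiconCascade


@pytest.fixture(scope="session")
def default_generation():
    """The default study-shaped synthetic corpus (81 migraine / 40 cluster)."""
    return generate_corpus(GeneratorConfig())


@pytest.fixture(scope="session")
def default_corpus(default_generation):
    return default_generation[0]


@pytest.fixture(scope="session")
def default_annotations(default_generation):
    return default_generation[1]


@pytest.fixture(scope="session")
def default_truth(default_generation):
    return default_generation[2]


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


@pytest.fixture(scope="session")
def blocklist():
    return default_blocklist()


@pytest.fixture(scope="session")
def toy_lexicons():
    return generate_lexicon_fixtures(GeneratorConfig())


@pytest.fixture(scope="session")
def toy_cascade(toy_lexicons):
    return LexiconCascade.from_lexicons(toy_lexicons)


@pytest.fixture(scope="session")
def attack_setup(default_generation, blocklist, stopwords):
    """Attack-description subcorpus (74/38) with ML-ready tokenization."""
    corpus, annotations, _ = default_generation
    docs_raw = tokenize_corpus(corpus)
    attacks = extract_theme_subcorpus(
        corpus, annotations, docs_raw, "attack_description"
    )
    docs_ml = preprocess_corpus(attacks, blocklist=blocklist, stopwords=stopwords)
    return attacks, docs_ml
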
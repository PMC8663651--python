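import pytest

from painlex.corpus_io import Post, clean_posts
from painlex.synthetic_corpus import CorpusConfig, PlantedLexicon, generate_corpus


def make_post(text: str, pid: str = "p1") -> Post:
    """A cleaned post from raw text."""
    return Post(id=pid, platform="twitter", timestamp="2019-06-01T00:00:00+00:00", text=text).with_tokens()


@pytest.fixture(scope="session")
def planted_lexicon() -> PlantedLexicon:
    return PlantedLexicon(
        root_descriptors=["stabbing", "burning", "aching"],
        associates={"stabbing": [("puncturing", 0.9), ("zorblax", 0.0)]},
        conditions=["migraine", "arthritis"],
        emotion_words={"fear": [("terrified", 0.8)]},
        sarcasm_markers=["totally", "obviously"],
    )


@pytest.fixture(scope="session")
def small_config(planted_lexicon) -> CorpusConfig:
    return CorpusConfig(
        n_posts=2000,
        planted_lexicon=planted_lexicon,
        p_contains_pain=0.7,
        p_sarcastic=0.05,
        p_username=0.3,
        p_url=0.2,
        noise_vocab_size=200,
        post_length_range=(5, 9),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    """2000 generated posts (cleaned) with their hidden labels."""
    corpus = generate_corpus(small_config)
    return clean_posts(corpus.posts), corpus.labels
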
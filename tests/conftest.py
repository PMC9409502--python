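import numpy as np
import pytest

from caremine import CorpusConfig, DutchPreprocessor, generate_corpus
from caremine.io import Utterance
from caremine.synthetic import make_pseudo_words


@pytest.fixture(scope="session")
def study_scale_corpus():
    """Default study-scale synthetic corpus (125 interviews) + ground truth."""
    return generate_corpus(CorpusConfig(seed=101))


@pytest.fixture(scope="session")
def small_corpus():
    """A small, fast corpus for per-module oracle checks."""
    cfg = CorpusConfig(
        seed=7,
        n_interviews_per_group={"resident": 4, "family": 4, "professional": 4},
        mean_words_per_interview={"resident": 120, "family": 140, "professional": 160},
        vocab_size=600,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_tokenized(small_corpus):
    utterances, _ = small_corpus
    return DutchPreprocessor().transform(utterances)


@pytest.fixture
def handmade_utterances():
    """Two tiny hand-written interviews with known content."""
    rows = [
        ("i1", "resident", "interviewer", 0, "Hoe gaat het met u vandaag?"),
        ("i1", "resident", "interviewee", 1, "Heel erg goed, de zorg is fijn."),
        ("i1", "resident", "interviewee", 2, "Het eten is lekker en de verpleegkundigen zijn lief."),
        ("i2", "family", "interviewer", 0, "Wat vindt u van de instelling?"),
        ("i2", "family", "interviewee", 1, "Mijn moeder is hier gelukkig."),
        ("i2", "family", "interviewee", 2, "Heel erg goed geregeld allemaal."),
    ]
    return [Utterance(*r) for r in rows]


def topic_corpus_config(seed, n_topics=5, kw_per_topic=10, share=0.4):
    """A corpus with well-separated planted topics for recovery tests."""
    rng = np.random.default_rng(999)
    words = make_pseudo_words(n_topics * kw_per_topic, rng)
    spec = [
        (f"topic{i}", words[i * kw_per_topic : (i + 1) * kw_per_topic], 1.0 / n_topics)
        for i in range(n_topics)
    ]
    return CorpusConfig(
        seed=seed,
        topic_spec=spec,
        topic_token_share=share,
        n_interviews_per_group={"resident": 15, "family": 15, "professional": 15},
        mean_words_per_interview={"resident": 350, "family": 350, "professional": 350},
    )
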
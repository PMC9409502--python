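import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caremine import (
    CorpusConfig,
    DutchPreprocessor,
    build_lexicon,
    evaluate_lexicon,
    generate_corpus,
    generate_survey,
)
from caremine.io import AnnotatedSentence
from caremine.lexicon import SentimentLexicon


def _ann(text, label, sid="s", aid="a"):
    return AnnotatedSentence(sentence_id=sid, text=text, label=label, annotator_id=aid)


def _fill(n, label, word="vulwoord"):
    """Padding sentences so min_occurrences never hides the term under test."""
    return [_ann(word, label, sid=f"pad{i}") for i in range(n)]


def test_worked_example_nine_positive_one_negative_scores_08():
    anns = [_ann("prachtig", "positive", sid=f"p{i}") for i in range(9)]
    anns.append(_ann("prachtig", "negative", sid="n0"))
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1,))
    e = lex.entries["prachtig"]
    assert (e.n_pos, e.n_neg, e.n_neu) == (9, 1, 0)
    assert e.score == 0.8


def test_term_only_in_positive_contexts_scores_one():
    anns = [_ann("prachtig", "positive", sid=f"p{i}") for i in range(5)]
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1,))
    assert lex.score("prachtig") == 1.0


def test_balanced_term_scores_zero():
    anns = (
        [_ann("gemengd", "positive", sid=f"p{i}") for i in range(4)]
        + [_ann("gemengd", "negative", sid=f"n{i}") for i in range(4)]
        + [_ann("gemengd", "neutral", sid=f"u{i}") for i in range(3)]
    )
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1,))
    assert lex.score("gemengd") == 0.0


def test_neutral_contexts_dilute_toward_zero():
    anns = [_ann("rustig", "positive", sid=f"p{i}") for i in range(5)] + [
        _ann("rustig", "neutral", sid=f"u{i}") for i in range(5)
    ]
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1,))
    assert lex.score("rustig") == 0.5


@given(
    n_pos=st.integers(0, 30),
    n_neg=st.integers(0, 30),
    n_neu=st.integers(0, 30),
)
@settings(max_examples=200, derandomize=True)
def test_score_formula_invariants(n_pos, n_neg, n_neu):
    total = n_pos + n_neg + n_neu
    if total < 1:
        return
    anns = (
        [_ann("woord", "positive", sid=f"p{i}") for i in range(n_pos)]
        + [_ann("woord", "negative", sid=f"n{i}") for i in range(n_neg)]
        + [_ann("woord", "neutral", sid=f"u{i}") for i in range(n_neu)]
    )
    lex = build_lexicon(anns, min_occurrences=1, ngram_orders=(1,))
    s = lex.score("woord")
    assert -1.0 <= s <= 1.0
    assert s == (n_pos - n_neg) / total
    assert (s == 1.0) == (n_neg == 0 and n_neu == 0)
    assert (s == -1.0) == (n_pos == 0 and n_neu == 0)


def test_label_flip_negates_every_score_exactly(small_corpus):
    utterances, truth = small_corpus
    survey = generate_survey(
        utterances, truth.planted_lexicon, n_sentences=100, n_annotators=20, seed=3
    )
    flip = {"positive": "negative", "negative": "positive", "neutral": "neutral"}
    flipped = [
        AnnotatedSentence(a.sentence_id, a.text, flip[a.label], a.annotator_id)
        for a in survey
    ]
    lex = build_lexicon(survey, min_occurrences=1)
    lex_f = build_lexicon(flipped, min_occurrences=1)
    assert set(lex.entries) == set(lex_f.entries)
    for t, e in lex.entries.items():
        assert lex_f.score(t) == -e.score


def test_duplicating_annotations_leaves_scores_unchanged(small_corpus):
    utterances, truth = small_corpus
    survey = generate_survey(
        utterances, truth.planted_lexicon, n_sentences=100, n_annotators=10, seed=5
    )
    lex = build_lexicon(survey, min_occurrences=1)
    lex2 = build_lexicon(survey + survey, min_occurrences=1)
    assert lex.scores() == lex2.scores()


def test_multiple_occurrences_count_per_occurrence_by_default():
    anns = _fill(3, "neutral") + [_ann("fijn fijn dagje", "positive", sid="x")]
    lex = build_lexicon(anns, min_occurrences=1, ngram_orders=(1,))
    assert lex.entries["fijn"].n_pos == 2
    lex1 = build_lexicon(anns, min_occurrences=1, ngram_orders=(1,), once_per_sentence=True)
    assert lex1.entries["fijn"].n_pos == 1


def test_bigram_entries_from_within_sentence_pairs():
    anns = [_ann("erg slecht geregeld", "negative", sid=f"s{i}") for i in range(3)]
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1, 2))
    assert lex.score("erg slecht") == -1.0
    assert "slecht geregeld" in lex.entries
    assert lex.entries["erg slecht"].order == 2


def test_min_occurrences_drops_rare_terms():
    anns = _fill(5, "positive") + [_ann("zeldzaam", "positive", sid="r")]
    lex = build_lexicon(anns, min_occurrences=3, ngram_orders=(1,))
    assert "zeldzaam" not in lex
    assert "vulwoord" in lex


def test_empty_annotations_raise():
    with pytest.raises(ValueError, match="empty"):
        build_lexicon([])


def test_unknown_label_raises():
    with pytest.raises(ValueError, match="positivee"):
        build_lexicon([_ann("hoi", "positivee")])


def test_evaluate_lexicon_identity_and_empty():
    truth = {"fijn": 0.5, "slecht": -0.5}
    lex = SentimentLexicon.from_scores(truth)
    assert evaluate_lexicon(lex, truth) == (0.0, 1.0)
    empty = SentimentLexicon()
    mae, cov = evaluate_lexicon(empty, truth)
    assert mae is None and cov == 0.0


def test_recovery_matches_bruteforce_oracle_noise_free():
    """Noise-free survey: the lexicon must reproduce, term for term, an
    independent recount that recomputes labels from the planted rule."""
    cfg = CorpusConfig(
        seed=23,
        topic_spec=[],
        n_sentiment_terms=60,
        sentiment_token_share=0.2,
        n_interviews_per_group={"resident": 20, "family": 20, "professional": 20},
        mean_words_per_interview={"resident": 300, "family": 300, "professional": 300},
    )
    utterances, truth = generate_corpus(cfg)
    pool = sum(u.speaker == "interviewee" for u in utterances)
    survey = generate_survey(
        utterances, truth.planted_lexicon, n_sentences=pool, n_annotators=30,
        label_noise=0.0, seed=29, annotators_per_sentence=2,
    )
    pre = DutchPreprocessor()
    lex = build_lexicon(survey, preprocessor=pre, min_occurrences=3, ngram_orders=(1,))
    counts: dict[str, list[int]] = {}
    for a in survey:
        for t in pre.transform_text(a.text):
            if t in truth.planted_lexicon:
                c = counts.setdefault(t, [0, 0, 0])
                c[0] += a.label == "positive"
                c[1] += a.label == "negative"
                c[2] += a.label == "neutral"
    n_checked = 0
    diffs = []
    for t, (p, n, u) in counts.items():
        if p + n + u >= 50 and t in lex:
            diffs.append(abs(lex.score(t) - (p - n) / (p + n + u)))
            n_checked += 1
    assert n_checked >= 50
    assert np.mean([d <= 0.15 for d in diffs]) >= 0.95
    assert max(diffs) == 0.0  # noise-free recovery is exact
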
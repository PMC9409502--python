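import numpy as np
import pytest
from sklearn.base import clone

from caremine import (
    CorpusConfig,
    DutchPreprocessor,
    LexiconSentimentClassifier,
    generate_corpus,
    group_dispersion,
    interview_ternary,
    score_sentence,
    unigram_frequencies,
    word_sentiment_scatter,
)
from caremine.lexicon import SentimentLexicon
from caremine.preprocess import TokenizedCorpus
from caremine.sentiment import TernaryPoint, match_terms


def _lex(scores):
    return SentimentLexicon.from_scores(scores)


def _corpus(per_interview):
    c = TokenizedCorpus()
    for iid, (group, utts) in per_interview.items():
        c.tokens[iid] = [list(u) for u in utts]
        c.bigram_tokens[iid] = [list(u) for u in utts]
        c.groups[iid] = group
        c.provenance[iid] = list(range(len(utts)))
    return c


def test_all_positive_terms_give_positive_class():
    s = score_sentence(["fijn", "mooi"], _lex({"fijn": 1.0, "mooi": 1.0}))
    assert s.label == "positive" and s.raw == 1.0 and s.n_matched_terms == 2


def test_no_matches_is_neutral_zero():
    s = score_sentence(["onbekend"], _lex({"fijn": 1.0}))
    assert s == type(s)(raw=0.0, label="neutral", n_matched_terms=0)


def test_raw_score_matches_sum_count_oracle():
    rng = np.random.default_rng(31)
    vocab = [f"w{i}" for i in range(50)]
    lex = _lex({w: float(s) for w, s in zip(vocab, rng.uniform(-1, 1, 50))})
    for _ in range(100):
        toks = list(rng.choice(vocab + ["xx", "yy"], size=rng.integers(1, 15)))
        s = score_sentence(toks, lex)
        matched = [t for t in toks if t in lex.entries]
        if matched:
            expected = sum(lex.score(t) for t in matched) / len(matched)
            assert s.raw == pytest.approx(expected, abs=1e-12)
        else:
            assert s.raw == 0.0


def test_bigram_match_suppresses_component_unigrams():
    lex = _lex({"goed": 1.0, "niet goed": -1.0})
    assert match_terms(["niet", "goed"], lex) == ["niet goed"]
    s = score_sentence(["niet", "goed"], lex)
    assert s.raw == -1.0 and s.label == "negative"
    # without the bigram context, 'goed' scores positively
    assert score_sentence(["goed"], lex).raw == 1.0


def test_invalid_tau_rejected():
    with pytest.raises(ValueError, match="tau"):
        score_sentence(["fijn"], _lex({"fijn": 1.0}), tau=0.0)


def test_interview_ternary_proportions():
    lex = _lex({"fijn": 1.0, "slecht": -1.0})
    c = _corpus(
        {"i1": ("resident", [["fijn"], ["fijn"], ["slecht"], ["onbekend"]])}
    )
    (p,) = interview_ternary(c, lex)
    assert (p.pct_positive, p.pct_negative, p.pct_neutral) == (50.0, 25.0, 25.0)


def test_empty_interview_raises_with_name():
    c = _corpus({"leeg-01": ("resident", [])})
    with pytest.raises(ValueError, match="leeg-01"):
        interview_ternary(c, _lex({"fijn": 1.0}))


def test_ternary_sums_to_100_on_synthetic_corpora():
    for seed in range(3):
        cfg = CorpusConfig(
            seed=seed,
            n_interviews_per_group={"resident": 3, "family": 3, "professional": 3},
            mean_words_per_interview={"resident": 60, "family": 60, "professional": 60},
            vocab_size=400,
        )
        utterances, truth = generate_corpus(cfg)
        corpus = DutchPreprocessor().transform(utterances)
        points = interview_ternary(corpus, _lex(truth.planted_lexicon))
        assert len(points) == 9
        for p in points:
            assert abs(p.pct_positive + p.pct_negative + p.pct_neutral - 100.0) <= 1e-9


def test_ternary_matches_recount_oracle(small_corpus, small_tokenized):
    _, truth = small_corpus
    lex = _lex(truth.planted_lexicon)
    points = {p.interview_id: p for p in interview_ternary(small_tokenized, lex)}
    for iid, utts in small_tokenized.tokens.items():
        labels = [score_sentence(u, lex).label for u in utts]
        n = len(labels)
        assert points[iid].pct_positive == pytest.approx(100 * labels.count("positive") / n)
        assert points[iid].pct_negative == pytest.approx(100 * labels.count("negative") / n)


def test_flipping_lexicon_sign_swaps_positive_and_negative(small_corpus, small_tokenized):
    _, truth = small_corpus
    lex = _lex(truth.planted_lexicon)
    flipped = _lex({t: -s for t, s in truth.planted_lexicon.items()})
    a = {p.interview_id: p for p in interview_ternary(small_tokenized, lex)}
    b = {p.interview_id: p for p in interview_ternary(small_tokenized, flipped)}
    for iid in a:
        assert a[iid].pct_positive == b[iid].pct_negative
        assert a[iid].pct_negative == b[iid].pct_positive
        assert a[iid].pct_neutral == pytest.approx(b[iid].pct_neutral, abs=1e-9)


def test_huge_tau_drives_everything_neutral(small_corpus, small_tokenized):
    _, truth = small_corpus
    points = interview_ternary(small_tokenized, _lex(truth.planted_lexicon), tau=1.0 + 1e-9)
    for p in points:
        assert (p.pct_positive, p.pct_negative, p.pct_neutral) == (0.0, 0.0, 100.0)


def test_ternary_point_rejects_bad_sum():
    with pytest.raises(ValueError, match="sum"):
        TernaryPoint("i1", "resident", 50.0, 30.0, 30.0)


def test_group_dispersion_degenerate_groups():
    pts = [
        TernaryPoint("a", "resident", 50.0, 25.0, 25.0),
        TernaryPoint("b", "resident", 50.0, 25.0, 25.0),
        TernaryPoint("c", "family", 80.0, 10.0, 10.0),
        TernaryPoint("d", "family", 20.0, 40.0, 40.0),
    ]
    disp = group_dispersion(pts)
    assert disp["resident"]["dispersion"] == 0.0
    xy_c = np.array(pts[2].barycentric_xy())
    xy_d = np.array(pts[3].barycentric_xy())
    assert disp["family"]["dispersion"] == pytest.approx(float(np.hypot(*(xy_c - xy_d))))
    assert disp["family"]["dispersion_rank"] == 1.0


def test_planted_group_dispersion_ordering_recovered(study_scale_corpus):
    """Generator plants resident < family < professional sentiment spread;
    the dispersion statistic must recover that ordering."""
    utterances, truth = study_scale_corpus
    corpus = DutchPreprocessor().transform(utterances)
    points = interview_ternary(corpus, _lex(truth.planted_lexicon))
    disp = group_dispersion(points)
    assert (
        disp["resident"]["dispersion"]
        < disp["family"]["dispersion"]
        < disp["professional"]["dispersion"]
    )


def test_word_sentiment_scatter_contract(small_corpus, small_tokenized):
    _, truth = small_corpus
    lex = _lex(truth.planted_lexicon)
    assert word_sentiment_scatter(small_tokenized, lex, top_n=0).empty
    frame = word_sentiment_scatter(small_tokenized, lex, top_n=10, scope="resident")
    table = unigram_frequencies(small_tokenized, "resident")
    for row in frame.itertuples():
        assert row.score == lex.score(row.term)  # verbatim from lexicon
        assert row.count == table.counts[row.term]  # consistent with frequency module
    assert set(frame["term"]) <= set(truth.planted_lexicon)


def test_classifier_fit_predict_roundtrip():
    texts = ["prachtig mooi", "vreselijk slecht", "tafel stoel"] * 5
    labels = ["positive", "negative", "neutral"] * 5
    clf = LexiconSentimentClassifier(min_occurrences=1, ngram_orders=(1,))
    clone(clf)  # sklearn param contract
    clf.fit(texts, labels)
    assert list(clf.predict(["prachtig", "vreselijk", "tafel"])) == [
        "positive",
        "negative",
        "neutral",
    ]
    raw = clf.decision_function(["prachtig mooi"])
    assert raw[0] == pytest.approx(1.0)
    assert set(clf.get_params()) >= {"tau", "min_occurrences", "ngram_orders"}


def test_classifier_requires_fit():
    clf = LexiconSentimentClassifier()
    with pytest.raises(AttributeError, match="not fitted"):
        clf.predict(["hoi"])
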
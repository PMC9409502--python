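import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from caremine import (
    DutchPreprocessor,
    KeywordTopicModel,
    choose_k,
    cluster_keywords,
    cluster_report,
    embed_keywords,
    extract_keywords,
    generate_corpus,
    project_2d,
)
from caremine.preprocess import TokenizedCorpus
from caremine.topics import (
    HeuristicDutchNounTagger,
    LexiconPOSTagger,
    knee_point,
)
from conftest import topic_corpus_config


def _corpus(per_interview):
    c = TokenizedCorpus()
    for iid, (group, utts) in per_interview.items():
        c.tokens[iid] = [list(u) for u in utts]
        c.bigram_tokens[iid] = [list(u) for u in utts]
        c.groups[iid] = group
        c.provenance[iid] = list(range(len(utts)))
    return c


def _blobs(n_per=20, centers=((0, 0), (10, 0), (0, 10)), seed=0, spread=0.5):
    rng = np.random.default_rng(seed)
    emb = {}
    for ci, c in enumerate(centers):
        for i in range(n_per):
            emb[f"c{ci}w{i}"] = np.array(c) + rng.normal(0, spread, 2)
    return emb


def test_extract_keywords_only_nouns():
    tagger = LexiconPOSTagger({"zuster": "NOUN", "lopen": "VERB", "mooi": "ADJ"})
    c = _corpus({"i1": ("resident", [["zuster", "lopen", "mooi", "zuster"]])})
    ks = extract_keywords(c, tagger)
    assert dict(ks.counts) == {"zuster": 2}
    assert ks.sources["zuster"] == {("i1", 0)}


def test_extract_keywords_no_nouns_empty():
    tagger = LexiconPOSTagger({}, default="VERB")
    c = _corpus({"i1": ("resident", [["lopen", "fietsen"]])})
    assert len(extract_keywords(c, tagger)) == 0


def test_extract_keywords_requires_tagger():
    c = _corpus({"i1": ("resident", [["x"]])})
    with pytest.raises(TypeError, match="tagger"):
        extract_keywords(c, None)


def test_planted_keywords_all_recovered_and_counts_consistent():
    cfg = topic_corpus_config(seed=2)
    utterances, truth = generate_corpus(cfg)
    corpus = DutchPreprocessor().transform(utterances)
    tagger = LexiconPOSTagger(truth.pos_tags)
    ks = extract_keywords(corpus, tagger)
    assert set(truth.topic_assignment) <= set(ks.counts)
    from caremine import unigram_frequencies

    table = unigram_frequencies(corpus, "all")
    for term, count in ks.counts.items():
        assert count == table.counts[term]


def test_heuristic_tagger_flags_derivational_nouns():
    t = HeuristicDutchNounTagger()
    assert t.tag("opleiding") == "NOUN"
    assert t.tag("vrijheid") == "NOUN"
    assert t.tag("goed") == "X"


def test_embeddings_cluster_shared_context_keywords():
    # aaa/bbb always co-occur, ccc/ddd always co-occur, never across
    utts = [["aaa", "bbb", "xxx"]] * 20 + [["ccc", "ddd", "yyy"]] * 20
    c = _corpus({"i1": ("resident", utts)})
    emb = embed_keywords(c, ["aaa", "bbb", "ccc", "ddd"], d=4, min_count=3)
    cos = lambda a, b: float(np.dot(emb[a], emb[b]))
    assert cos("aaa", "bbb") > cos("aaa", "ccc")
    assert cos("ccc", "ddd") > cos("bbb", "ddd")


def test_embed_excludes_below_min_count():
    utts = [["aaa", "bbb"]] * 10 + [["zzz", "aaa"]]
    c = _corpus({"i1": ("resident", utts)})
    emb = embed_keywords(c, ["aaa", "bbb", "zzz"], d=2, min_count=3)
    assert "zzz" not in emb and "aaa" in emb


def test_embed_deterministic(small_tokenized):
    kws = sorted(
        t for t, c in __import__("collections").Counter(
            small_tokenized.flat_tokens()
        ).items() if c >= 5
    )[:40]
    e1 = embed_keywords(small_tokenized, kws, d=10)
    e2 = embed_keywords(small_tokenized, kws, d=10)
    assert set(e1) == set(e2)
    for t in e1:
        assert np.array_equal(e1[t], e2[t])


def test_knee_point_linear_curve_returns_smallest_interior():
    ks = [2, 3, 4, 5, 6]
    w = [100.0, 80.0, 60.0, 40.0, 20.0]
    assert knee_point(ks, w) == 3


def test_knee_point_obvious_elbow():
    ks = [1, 2, 3, 4, 5, 6]
    w = [100.0, 60.0, 10.0, 8.0, 6.0, 4.0]
    assert knee_point(ks, w) == 3


def test_choose_k_requires_three_values():
    with pytest.raises(ValueError, match=">= 3"):
        choose_k(_blobs(), [2, 3])


def test_choose_k_three_separated_blobs():
    assert choose_k(_blobs(seed=1), range(2, 9)) == 3


def test_cluster_keywords_edges():
    emb = _blobs(n_per=3)
    one, w1 = cluster_keywords(emb, k=1)
    assert set(one.values()) == {1}
    singletons, w0 = cluster_keywords(emb, k=len(emb))
    assert sorted(singletons.values()) == list(range(1, len(emb) + 1))
    assert w0 == pytest.approx(0.0, abs=1e-12)


def test_kmeans_beats_random_assignments():
    emb = _blobs(seed=3)
    terms = sorted(emb)
    X = np.vstack([emb[t] for t in terms])
    _, w = cluster_keywords(emb, k=3, seed=0)
    rng = np.random.default_rng(0)
    for _ in range(100):
        labels = rng.integers(0, 3, len(terms))
        w_rand = 0.0
        for lab in range(3):
            pts = X[labels == lab]
            if len(pts):
                w_rand += float(((pts - pts.mean(axis=0)) ** 2).sum())
        assert w <= w_rand + 1e-9


def test_project_2d_contract():
    emb = _blobs(seed=5)
    coords = project_2d(emb)
    assert set(coords) == set(emb)
    # 2-D input: projection preserves pairwise distances (rigid motion)
    a, b = "c0w0", "c1w0"
    d_in = np.linalg.norm(emb[a] - emb[b])
    d_out = np.hypot(
        coords[a][0] - coords[b][0], coords[a][1] - coords[b][1]
    )
    assert d_out == pytest.approx(d_in, rel=1e-9)


def test_cluster_report_conserves_counts():
    from caremine.topics import KeywordSet
    from collections import Counter

    ks = KeywordSet(
        counts=Counter({"aaa": 5, "bbb": 3, "ccc": 2}),
        sources={"aaa": {("i1", 0)}, "bbb": {("i1", 0), ("i1", 1)}, "ccc": {("i2", 0)}},
    )
    report = cluster_report({"aaa": 1, "bbb": 1, "ccc": 2}, ks, top_m=2)
    assert report["total_occurrences"].sum() == 10
    assert list(report["cluster_id"]) == [1, 2]
    row1 = report[report.cluster_id == 1].iloc[0]
    assert row1["top_keywords"] == "aaa, bbb"
    assert row1["n_sentences"] == 2
    singletons = cluster_report({"aaa": 1, "bbb": 2, "ccc": 3}, ks)
    assert list(singletons["total_occurrences"]) == [5, 3, 2]


@pytest.mark.parametrize("n_topics", [3, 5, 12])
def test_topic_recovery_ari(n_topics):
    """Planted, well-separated topics are recovered with high agreement."""
    aris = []
    for seed in range(5):
        kw_per = 6 if n_topics == 12 else 10
        cfg = topic_corpus_config(seed=seed, n_topics=n_topics, kw_per_topic=kw_per)
        utterances, truth = generate_corpus(cfg)
        corpus = DutchPreprocessor().transform(utterances)
        tagger = LexiconPOSTagger({k: "NOUN" for k in truth.topic_assignment})
        model = KeywordTopicModel(
            tagger=tagger, k=n_topics, random_state=seed
        )
        model.fit(corpus)
        lab_true = [truth.topic_assignment[t] for t in model.terms_]
        aris.append(adjusted_rand_score(lab_true, model.labels_))
    assert np.median(aris) >= 0.8


def test_model_fit_is_bitwise_reproducible():
    cfg = topic_corpus_config(seed=4)
    utterances, truth = generate_corpus(cfg)
    corpus = DutchPreprocessor().transform(utterances)
    tagger = LexiconPOSTagger({k: "NOUN" for k in truth.topic_assignment})
    runs = []
    for _ in range(2):
        m = KeywordTopicModel(tagger=tagger, k="auto", k_range=(2, 8), random_state=7)
        m.fit(corpus)
        runs.append(m)
    a, b = runs
    assert a.k_ == b.k_
    assert a.assignments_ == b.assignments_
    assert a.projection_ == b.projection_
    for t in a.embeddings_:
        assert np.array_equal(a.embeddings_[t], b.embeddings_[t])


def test_model_report_requires_fit():
    with pytest.raises(AttributeError, match="not fitted"):
        KeywordTopicModel().report()
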
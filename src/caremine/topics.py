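"""Keyword topic clustering.

Nouns carry most of the thematic content of interview text, so topic
discovery proceeds in four steps: (1) extract noun/proper-noun keywords
from interviewee utterances with a pluggable POS tagger; (2) embed each
keyword as a distributional vector — positive pointwise mutual
information (PPMI) against windowed co-occurrence contexts, reduced by
SVD — so keywords used in similar contexts sit close together; (3)
cluster the vectors with k-means, choosing k by the elbow (knee) of the
within-cluster sum-of-squares curve; (4) report per-cluster top keywords
and occurrence totals, plus a 2-D projection for plotting.

The embedding is fully deterministic: co-occurrence counting and dense
SVD involve no sampling, and k-means is seeded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .preprocess import TokenizedCorpus

logger = logging.getLogger(__name__)

NOUN_TAGS = ("NOUN", "PROPN")


class Tagger(Protocol):
    def tag(self, token: str) -> str: ...


class LexiconPOSTagger:
    """Dictionary-backed tagger: token → tag, with a default for unknowns."""

    def __init__(self, mapping: Mapping[str, str], default: str = "X"):
        self.mapping = dict(mapping)
        self.default = default

    def tag(self, token: str) -> str:
        return self.mapping.get(token, self.default)


class HeuristicDutchNounTagger:
    """Suffix-heuristic noun detector for Dutch stems.

    Derivational suffixes like -heid, -ing, -tie, -teit, -schap, -sel,
    -aar and -eur almost always mark nouns; everything else is tagged X.
    Crude, but useful when no trained tagger is available.
    """

    _NOUN_SUFFIXES = (
        "heid", "ing", "tie", "sie", "teit", "schap", "dom", "sel",
        "aar", "eur", "ier", "iek", "ment", "isme", "age", "uur",
    )

    def tag(self, token: str) -> str:
        if any(token.endswith(s) for s in self._NOUN_SUFFIXES) and len(token) > 4:
            return "NOUN"
        return "X"


class SpacyTaggerAdapter:
    """Adapter for a full statistical tagger; raises with an install hint
    when the model is unavailable."""

    def __init__(self, model: str = "nl_core_news_sm"):
        try:
            import spacy  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "POS tagger unavailable: spaCy is not installed. "
                "Install it with `pip install spacy` and download the Dutch "
                f"model with `python -m spacy download {model}`, or pass a "
                "LexiconPOSTagger / HeuristicDutchNounTagger instead."
            ) from exc
        self._nlp = spacy.load(model, disable=["parser", "ner", "lemmatizer"])

    def tag(self, token: str) -> str:
        doc = self._nlp(token)
        return doc[0].pos_ if len(doc) else "X"


@dataclass
class KeywordSet:
    """Noun keywords with corpus occurrence counts and source references."""

    counts: Counter = field(default_factory=Counter)
    sources: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def terms(self) -> list[str]:
        return sorted(self.counts)


def extract_keywords(corpus: TokenizedCorpus, tagger: Tagger) -> KeywordSet:
    """Stemmed noun/proper-noun tokens from interviewee utterances.

    Counts are exact token-occurrence totals over the preprocessed
    corpus, so they agree with the frequency tables restricted to the
    keyword vocabulary; ``sources`` records (interview, utterance index)
    of every occurrence.
    """
    if tagger is None or not hasattr(tagger, "tag"):
        raise TypeError("a tagger with a .tag(token) -> str method is required")
    ks = KeywordSet()
    tag_cache: dict[str, bool] = {}
    for iid, utts in corpus.tokens.items():
        for ui, utt in enumerate(utts):
            for tok in utt:
                is_noun = tag_cache.get(tok)
                if is_noun is None:
                    is_noun = tagger.tag(tok) in NOUN_TAGS
                    tag_cache[tok] = is_noun
                if is_noun:
                    ks.counts[tok] += 1
                    ks.sources.setdefault(tok, set()).add((iid, ui))
    return ks


def embed_keywords(
    corpus: TokenizedCorpus,
    keywords: Sequence[str],
    d: int = 50,
    window: int = 5,
    min_count: int = 3,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """PPMI–SVD distributional vectors for the given keywords.

    Co-occurrence is counted within a symmetric ``window`` inside each
    utterance (never across turns).  Keywords below ``min_count`` corpus
    occurrences are excluded (and logged).  Rows are L2-normalized so
    Euclidean k-means approximates cosine geometry.  The computation is
    deterministic; ``seed`` is accepted for interface symmetry only.
    """
    if d < 2:
        raise ValueError("embedding dimension d must be >= 2")
    if window < 1:
        raise ValueError("window must be >= 1")
    token_counts: Counter = Counter()
    for utt in corpus.utterances_in_scope("all"):
        token_counts.update(utt)
    kept = [k for k in keywords if token_counts[k] >= min_count]
    dropped = [k for k in keywords if token_counts[k] < min_count]
    if dropped:
        logger.info(
            "embed_keywords: excluded %d keywords below min_count=%d: %s",
            len(dropped),
            min_count,
            ", ".join(sorted(dropped)[:10]),
        )
    if len(kept) < 2:
        raise ValueError(
            f"need >= 2 keywords with >= {min_count} occurrences, got {len(kept)}"
        )
    contexts = sorted(t for t, c in token_counts.items() if c >= min_count)
    ctx_index = {t: j for j, t in enumerate(contexts)}
    kw_index = {t: i for i, t in enumerate(kept)}

    cooc = np.zeros((len(kept), len(contexts)))
    col_counts = np.zeros(len(contexts))
    total_pairs = 0
    for utt in corpus.utterances_in_scope("all"):
        n = len(utt)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            ci = kw_index.get(utt[i], -1)
            for j in range(lo, hi):
                if j == i:
                    continue
                total_pairs += 1
                cj = ctx_index.get(utt[j])
                if cj is not None:
                    col_counts[cj] += 1
                    if ci >= 0:
                        cooc[ci, cj] += 1
    if total_pairs == 0:
        raise ValueError("corpus has no co-occurrence pairs")
    row_marg = cooc.sum(axis=1, keepdims=True)
    row_marg[row_marg == 0] = 1.0
    col_safe = np.where(col_counts == 0, 1.0, col_counts)
    with np.errstate(divide="ignore"):
        pmi = np.log((cooc * total_pairs) / (row_marg * col_safe[None, :]))
    ppmi = np.where(cooc > 0, np.maximum(pmi, 0.0), 0.0)

    d_eff = min(d, min(ppmi.shape) - 1) if min(ppmi.shape) > 1 else 1
    u, s, _ = linalg.svd(ppmi, full_matrices=False)
    vecs = u[:, :d_eff] * np.sqrt(s[:d_eff])[None, :]
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, j]))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vecs = vecs / norms
    return {kept[i]: vecs[i] for i in range(len(kept))}


def _stack(embeddings: Mapping[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    terms = sorted(embeddings)
    return terms, np.vstack([embeddings[t] for t in terms])


def wss_curve(
    embeddings: Mapping[str, np.ndarray],
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 10,
) -> dict[int, float]:
    """Within-cluster sum of squares W(k) for each candidate k."""
    _, X = _stack(embeddings)
    out: dict[int, float] = {}
    for k in k_range:
        if not 1 <= k <= len(X):
            raise ValueError(f"k={k} outside [1, {len(X)}]")
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        km.fit(X)
        out[k] = float(km.inertia_)
    return out


def knee_point(ks: Sequence[int], w: Sequence[float]) -> int:
    """Max-distance-to-chord knee of a (k, W(k)) curve.

    Both axes are min-max normalized before measuring perpendicular
    distance to the chord joining the endpoints, so the rule is
    scale-free.  Only interior points are candidates; ties break toward
    the smallest k, so a perfectly linear curve returns the smallest
    interior k.
    """
    if len(ks) != len(w):
        raise ValueError("ks and w must align")
    if len(ks) < 3:
        raise ValueError(f"need >= 3 curve points, got {len(ks)}")
    x = np.array(ks, dtype=float)
    wv = np.array(w, dtype=float)
    x_n = (x - x[0]) / (x[-1] - x[0])
    denom = wv[0] - wv[-1]
    w_n = (wv - wv[-1]) / denom if denom != 0 else np.zeros_like(wv)
    p0 = np.array([x_n[0], w_n[0]])
    p1 = np.array([x_n[-1], w_n[-1]])
    chord = p1 - p0
    chord_len = np.hypot(*chord)
    dists = np.abs((x_n - p0[0]) * chord[1] - (w_n - p0[1]) * chord[0]) / chord_len
    interior = dists[1:-1]
    best_local = int(np.argmax(interior))  # argmax takes first = smallest k
    return int(ks[1 + best_local])


def choose_k(
    embeddings: Mapping[str, np.ndarray],
    k_range: Sequence[int],
    seed: int = 0,
    restarts: int = 10,
) -> int:
    """Elbow selection: the interior k whose point on the (k, W(k)) curve
    lies farthest from the chord joining the curve's endpoints (see
    :func:`knee_point`)."""
    ks = sorted(set(k_range))
    if len(ks) < 3:
        raise ValueError(f"k_range needs >= 3 distinct values, got {len(ks)}")
    curve = wss_curve(embeddings, ks, seed=seed, restarts=restarts)
    return knee_point(ks, [curve[k] for k in ks])


def cluster_keywords(
    embeddings: Mapping[str, np.ndarray],
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[dict[str, int], float]:
    """k-means (k-means++ seeding, best of ``restarts``) on the vectors.

    Returns (term → cluster id in 1..k, within-cluster sum of squares).
    """
    terms, X = _stack(embeddings)
    if not 1 <= k <= len(terms):
        raise ValueError(f"k={k} outside [1, {len(terms)}]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return {t: int(l) + 1 for t, l in zip(terms, labels)}, float(km.inertia_)


def project_2d(
    embeddings: Mapping[str, np.ndarray], seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D projection (PCA) for visualization.

    The axes have no intrinsic meaning; only relative distances do.  The
    Spearman rank correlation between 2-D and full-dimensional pairwise
    distances is logged as a distortion diagnostic.
    """
    terms, X = _stack(embeddings)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = linalg.svd(Xc, full_matrices=False)
    ncomp = min(2, u.shape[1])
    coords = u[:, :ncomp] * s[:ncomp][None, :]
    if ncomp < 2:
        coords = np.column_stack([coords, np.zeros(len(terms))])
    for j in range(2):
        pivot = np.argmax(np.abs(coords[:, j]))
        if coords[pivot, j] < 0:
            coords[:, j] = -coords[:, j]
    if len(terms) >= 4 and X.shape[1] >= 2:
        from scipy.spatial.distance import pdist

        rho = stats.spearmanr(pdist(X), pdist(coords)).statistic
        logger.info("project_2d: pairwise-distance rank correlation = %.3f", rho)
    return {t: (float(coords[i, 0]), float(coords[i, 1])) for i, t in enumerate(terms)}


def cluster_report(
    assignments: Mapping[str, int],
    keyword_set: KeywordSet,
    top_m: int = 5,
) -> pd.DataFrame:
    """Per-cluster summary: top keywords and occurrence totals.

    ``total_occurrences`` sums keyword-token occurrences over the
    cluster's keywords; ``n_sentences`` counts the distinct utterances in
    which any of them appeared (both readings of a cluster's size are
    reported).  Rows are ordered by cluster id and conserve the corpus
    keyword total exactly.
    """
    clusters: dict[int, list[str]] = {}
    for term, cid in assignments.items():
        clusters.setdefault(cid, []).append(term)
    rows = []
    for cid in sorted(clusters):
        terms = clusters[cid]
        ranked = sorted(terms, key=lambda t: (-keyword_set.counts[t], t))
        sentences: set[tuple[str, int]] = set()
        for t in terms:
            sentences |= keyword_set.sources.get(t, set())
        rows.append(
            {
                "cluster_id": cid,
                "n_keywords": len(terms),
                "top_keywords": ", ".join(ranked[:top_m]),
                "total_occurrences": int(sum(keyword_set.counts[t] for t in terms)),
                "n_sentences": len(sentences),
            }
        )
    return pd.DataFrame(rows)


class KeywordTopicModel(ClusterMixin, BaseEstimator):
    """End-to-end keyword topic clustering as a fittable estimator.

    ``fit`` takes a :class:`~caremine.preprocess.TokenizedCorpus`,
    extracts noun keywords with ``tagger``, embeds them (PPMI–SVD),
    selects k by the elbow rule when ``k="auto"``, clusters with k-means,
    and stores ``keywords_``, ``embeddings_``, ``labels_`` (aligned with
    ``terms_``), ``k_``, ``projection_`` and ``wss_curve_``.
    """

    def __init__(
        self,
        tagger: Tagger | None = None,
        d: int = 50,
        window: int = 5,
        min_count: int = 3,
        k: int | str = "auto",
        k_range: tuple[int, int] = (2, 20),
        restarts: int = 10,
        random_state: int = 0,
    ):
        self.tagger = tagger
        self.d = d
        self.window = window
        self.min_count = min_count
        self.k = k
        self.k_range = k_range
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X: TokenizedCorpus, y=None):
        tagger = self.tagger if self.tagger is not None else HeuristicDutchNounTagger()
        self.keywords_ = extract_keywords(X, tagger)
        if len(self.keywords_) < 2:
            raise ValueError("fewer than 2 noun keywords extracted; nothing to cluster")
        self.embeddings_ = embed_keywords(
            X,
            self.keywords_.terms(),
            d=self.d,
            window=self.window,
            min_count=self.min_count,
            seed=self.random_state,
        )
        if self.k == "auto":
            lo, hi = self.k_range
            hi = min(hi, len(self.embeddings_) - 1)
            ks = list(range(lo, hi + 1))
            self.wss_curve_ = wss_curve(
                self.embeddings_, ks, seed=self.random_state, restarts=self.restarts
            )
            self.k_ = choose_k(
                self.embeddings_, ks, seed=self.random_state, restarts=self.restarts
            )
        else:
            self.k_ = int(self.k)
            self.wss_curve_ = {}
        assignments, self.inertia_ = cluster_keywords(
            self.embeddings_, self.k_, seed=self.random_state, restarts=self.restarts
        )
        self.assignments_ = assignments
        self.terms_ = sorted(assignments)
        self.labels_ = np.array([assignments[t] for t in self.terms_])
        self.projection_ = project_2d(self.embeddings_, seed=self.random_state)
        return self

    def report(self, top_m: int = 5) -> pd.DataFrame:
        if not hasattr(self, "assignments_"):
            raise AttributeError("KeywordTopicModel is not fitted yet")
        return cluster_report(self.assignments_, self.keywords_, top_m=top_m)
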
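"""Lexicon-based sentence and interview sentiment scoring.

A sentence's raw score is the mean lexicon score of its matched terms
(bigram matches take precedence over their component unigrams, so 'niet
goed' is not double-counted as 'niet' + 'goed').  The raw score is
thresholded into a ternary class: positive above +τ, negative below −τ,
neutral otherwise (and for sentences with no lexicon match at all).
Per interview, the class proportions of its sentences form a point on
the 2-simplex — positive% + negative% + neutral% = 100 — the coordinates
of the classic ternary plot.  Group dispersion (how varied one speaker
group's interviews are in expressed sentiment) is the mean pairwise
Euclidean distance between that group's points in 2-D barycentric
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .frequency import unigram_frequencies
from .io import AnnotatedSentence
from .lexicon import SentimentLexicon, build_lexicon
from .preprocess import DutchPreprocessor, TokenizedCorpus


@dataclass(frozen=True, slots=True)
class SentenceScore:
    raw: float
    label: str  # positive | neutral | negative
    n_matched_terms: int


@dataclass(frozen=True, slots=True)
class TernaryPoint:
    interview_id: str
    group: str
    pct_positive: float
    pct_negative: float
    pct_neutral: float

    def __post_init__(self):
        s = self.pct_positive + self.pct_negative + self.pct_neutral
        if abs(s - 100.0) > 1e-9:
            raise ValueError(
                f"ternary percentages for {self.interview_id!r} sum to {s}, not 100"
            )

    def barycentric_xy(self) -> tuple[float, float]:
        """Project onto the 2-D plane of the ternary plot (unit triangle)."""
        b = self.pct_negative / 100.0
        c = self.pct_neutral / 100.0
        return b + c / 2.0, c * math.sqrt(3.0) / 2.0


def classify(raw: float, tau: float) -> str:
    if tau <= 0:
        raise ValueError(f"neutral band half-width tau must be > 0, got {tau}")
    if raw > tau:
        return "positive"
    if raw < -tau:
        return "negative"
    return "neutral"


def match_terms(tokens: Sequence[str], lexicon: SentimentLexicon) -> list[str]:
    """Greedy left-to-right matching; a matched bigram suppresses both of
    its component unigrams."""
    matched: list[str] = []
    bigrams = lexicon.bigrams()
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and bigrams and f"{tokens[i]} {tokens[i + 1]}" in bigrams:
            matched.append(f"{tokens[i]} {tokens[i + 1]}")
            i += 2
            continue
        if tokens[i] in lexicon:
            matched.append(tokens[i])
        i += 1
    return matched


def score_sentence(
    tokens: Sequence[str],
    lexicon: SentimentLexicon,
    tau: float = 0.1,
    aggregate: str = "mean",
) -> SentenceScore:
    """Score one preprocessed sentence against the lexicon.

    ``aggregate`` is "mean" (default) or "sum" over matched term scores;
    zero matches give a neutral sentence with raw score 0.
    """
    if tau <= 0:
        raise ValueError(f"neutral band half-width tau must be > 0, got {tau}")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    matched = match_terms(tokens, lexicon)
    if not matched:
        return SentenceScore(raw=0.0, label="neutral", n_matched_terms=0)
    total = sum(lexicon.score(t) for t in matched)
    raw = total / len(matched) if aggregate == "mean" else total
    return SentenceScore(raw=raw, label=classify(raw, tau), n_matched_terms=len(matched))


def interview_ternary(
    corpus: TokenizedCorpus,
    lexicon: SentimentLexicon,
    tau: float = 0.1,
    aggregate: str = "mean",
) -> list[TernaryPoint]:
    """Ternary sentiment proportions for every interview in the corpus.

    The sentence unit is the utterance.  Neutral% is computed as the
    complement so the three percentages sum to exactly 100.
    """
    points: list[TernaryPoint] = []
    for iid in corpus.tokens:
        utts = corpus.tokens[iid]
        if not utts:
            raise ValueError(f"interview {iid!r} has no interviewee sentences")
        labels = [score_sentence(u, lexicon, tau=tau, aggregate=aggregate).label for u in utts]
        n = len(labels)
        pos = 100.0 * labels.count("positive") / n
        neg = 100.0 * labels.count("negative") / n
        points.append(
            TernaryPoint(
                interview_id=iid,
                group=corpus.groups[iid],
                pct_positive=pos,
                pct_negative=neg,
                pct_neutral=100.0 - (pos + neg),
            )
        )
    return points


def ternary_frame(points: Sequence[TernaryPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "interview_id": [p.interview_id for p in points],
            "group": [p.group for p in points],
            "pct_positive": [p.pct_positive for p in points],
            "pct_negative": [p.pct_negative for p in points],
            "pct_neutral": [p.pct_neutral for p in points],
        }
    )


def group_dispersion(
    points: Sequence[TernaryPoint],
) -> dict[str, dict[str, float]]:
    """Per-group mean ternary point and mean pairwise distance.

    Distances are Euclidean in 2-D barycentric coordinates of the
    percentage simplex (scale: the plot triangle has unit sides when
    percentages are divided by 100).  Groups with a single interview get
    dispersion 0.  The returned mapping also carries each group's rank,
    1 = most dispersed.
    """
    by_group: dict[str, list[TernaryPoint]] = {}
    for p in points:
        by_group.setdefault(p.group, []).append(p)
    out: dict[str, dict[str, float]] = {}
    for grp, pts in by_group.items():
        xy = np.array([p.barycentric_xy() for p in pts])
        n = len(pts)
        if n < 2:
            disp = 0.0
        else:
            d = 0.0
            for i in range(n):
                d += float(np.sum(np.hypot(xy[i + 1 :, 0] - xy[i, 0], xy[i + 1 :, 1] - xy[i, 1])))
            disp = d / (n * (n - 1) / 2)
        out[grp] = {
            "n_interviews": float(n),
            "mean_pct_positive": float(np.mean([p.pct_positive for p in pts])),
            "mean_pct_negative": float(np.mean([p.pct_negative for p in pts])),
            "mean_pct_neutral": float(np.mean([p.pct_neutral for p in pts])),
            "dispersion": disp,
        }
    for rank, grp in enumerate(
        sorted(out, key=lambda g: (-out[g]["dispersion"], g)), start=1
    ):
        out[grp]["dispersion_rank"] = float(rank)
    return out


def word_sentiment_scatter(
    corpus: TokenizedCorpus,
    lexicon: SentimentLexicon,
    top_n: int = 40,
    scope: str = "all",
) -> pd.DataFrame:
    """(term, frequency, score) for the scope's most frequent lexicon terms.

    Terms absent from the lexicon are omitted before the top-n cut, so
    the table always holds min(top_n, covered vocabulary) rows — the
    plot-ready data behind a frequency-vs-sentiment word scatter.
    """
    if top_n < 0:
        raise ValueError("top_n must be non-negative")
    table = unigram_frequencies(corpus, scope)
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [(t, c, lexicon.score(t)) for t, c in ranked if t in lexicon][:top_n]
    return pd.DataFrame(rows, columns=["term", "count", "score"]).assign(scope=scope)


class LexiconSentimentClassifier(ClassifierMixin, BaseEstimator):
    """Ternary sentence-sentiment classifier backed by a survey lexicon.

    ``fit`` consumes annotated sentences (either
    :class:`~caremine.io.AnnotatedSentence` records, or raw texts plus a
    label vector ``y``) and builds the frequency-of-context lexicon;
    ``decision_function`` returns raw scores in [−1, 1] and ``predict``
    the thresholded ternary labels.

    Parameters
    ----------
    tau : float, default 0.1
        Half-width of the neutral band around 0.
    min_occurrences : int, default 3
        Minimum survey contexts for a term to enter the lexicon.
    ngram_orders : tuple, default (1, 2)
        Lexicon entry sizes; bigram matches suppress component unigrams.
    aggregate : str, default "mean"
        Sentence aggregation over matched term scores ("mean" or "sum").
    """

    def __init__(
        self,
        tau: float = 0.1,
        min_occurrences: int = 3,
        ngram_orders: tuple[int, ...] = (1, 2),
        aggregate: str = "mean",
        once_per_sentence: bool = False,
        preprocessor: DutchPreprocessor | None = None,
    ):
        self.tau = tau
        self.min_occurrences = min_occurrences
        self.ngram_orders = ngram_orders
        self.aggregate = aggregate
        self.once_per_sentence = once_per_sentence
        self.preprocessor = preprocessor

    def _pre(self) -> DutchPreprocessor:
        return self.preprocessor if self.preprocessor is not None else DutchPreprocessor()

    def fit(self, X: Sequence, y: Sequence[str] | None = None):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        X = list(X)
        if y is not None:
            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            annotations = [
                AnnotatedSentence(
                    sentence_id=str(i), text=t, label=lab, annotator_id="0"
                )
                for i, (t, lab) in enumerate(zip(X, y))
            ]
        else:
            annotations = X
        self.lexicon_ = build_lexicon(
            annotations,
            preprocessor=self._pre(),
            min_occurrences=self.min_occurrences,
            ngram_orders=tuple(self.ngram_orders),
            once_per_sentence=self.once_per_sentence,
        )
        self.classes_ = np.array(["negative", "neutral", "positive"])
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        pre = self._pre()
        return np.array(
            [
                score_sentence(
                    pre.transform_text(t), self.lexicon_, tau=self.tau, aggregate=self.aggregate
                ).raw
                for t in X
            ]
        )

    def predict(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        return np.array([classify(r, self.tau) for r in self.decision_function(X)])

    def _check_fitted(self) -> None:
        if not hasattr(self, "lexicon_"):
            raise AttributeError(
                "this LexiconSentimentClassifier is not fitted yet; call fit first"
            )
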
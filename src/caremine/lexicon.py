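"""Survey-derived sentiment lexicon.

Each term's sentiment is the frequency-of-context score

    score = (n_pos − n_neg) / (n_pos + n_neg + n_neu)

where n_pos / n_neg / n_neu count how often the term occurred in a
sentence judged positive / negative / neutral by an annotator.  A term
seen 9 times in positive contexts and once in a negative context scores
(9·1 + 1·(−1)) / 10 = 0.8.  Scores live in [−1, 1]: +1 means the term
appeared only in positive contexts, −1 only in negative ones, and
neutral contexts pull the score toward 0 through the denominator.

Every (sentence, annotator) judgement is one context; conflicting
annotator labels on the same sentence all count, with no adjudication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AnnotatedSentence
from .preprocess import DutchPreprocessor


@dataclass(frozen=True, slots=True)
class LexiconEntry:
    score: float
    n_pos: int
    n_neg: int
    n_neu: int
    order: int  # 1 = unigram, 2 = bigram


@dataclass
class SentimentLexicon:
    """term → (score in [−1, 1], supporting context counts)."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    ngram_orders: tuple[int, ...] = (1, 2)
    min_occurrences: int = 3

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def score(self, term: str) -> float:
        return self.entries[term].score

    def scores(self) -> dict[str, float]:
        return {t: e.score for t, e in self.entries.items()}

    def bigrams(self) -> set[str]:
        return {t for t, e in self.entries.items() if e.order == 2}

    @classmethod
    def from_scores(
        cls, scores: Mapping[str, float], ngram_orders: tuple[int, ...] = (1,)
    ) -> "SentimentLexicon":
        """Wrap a plain term → score map (e.g. a planted ground-truth
        lexicon) so it can drive the sentence scorer; context counts are
        zero because no survey backs it."""
        entries = {}
        for t, s in scores.items():
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"score for {t!r} outside [-1, 1]: {s}")
            entries[t] = LexiconEntry(
                score=float(s), n_pos=0, n_neg=0, n_neu=0, order=len(t.split())
            )
        return cls(entries=entries, ngram_orders=ngram_orders, min_occurrences=0)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries.items())
        return pd.DataFrame(
            {
                "term": [t for t, _ in rows],
                "ngram_order": [e.order for _, e in rows],
                "score": [e.score for _, e in rows],
                "n_pos": [e.n_pos for _, e in rows],
                "n_neg": [e.n_neg for _, e in rows],
                "n_neu": [e.n_neu for _, e in rows],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SentimentLexicon":
        entries = {
            str(r.term): LexiconEntry(
                score=float(r.score),
                n_pos=int(r.n_pos),
                n_neg=int(r.n_neg),
                n_neu=int(r.n_neu),
                order=int(r.ngram_order),
            )
            for r in frame.itertuples()
        }
        orders = tuple(sorted({e.order for e in entries.values()})) or (1,)
        return cls(entries=entries, ngram_orders=orders)


def _sentence_terms(
    tokens: Sequence[str], ngram_orders: Iterable[int], once_per_sentence: bool
) -> list[str]:
    terms: list[str] = []
    if 1 in ngram_orders:
        terms.extend(tokens)
    if 2 in ngram_orders:
        terms.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    if once_per_sentence:
        terms = sorted(set(terms))
    return terms


def build_lexicon(
    annotations: Sequence[AnnotatedSentence],
    preprocessor: DutchPreprocessor | None = None,
    min_occurrences: int = 3,
    ngram_orders: tuple[int, ...] = (1, 2),
    once_per_sentence: bool = False,
) -> SentimentLexicon:
    """Build a sentiment lexicon from sentence-level annotations.

    Each annotation record contributes one context per occurrence of a
    term in its (preprocessed) sentence — a word used twice in one
    sentence counts twice unless ``once_per_sentence``.  Terms with fewer
    than ``min_occurrences`` total contexts are dropped.
    """
    if not annotations:
        raise ValueError("cannot build a lexicon from an empty annotation set")
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    bad = set(ngram_orders) - {1, 2}
    if bad:
        raise ValueError(f"unsupported ngram orders: {sorted(bad)}")
    pre = preprocessor if preprocessor is not None else DutchPreprocessor()
    counts: dict[str, list[int]] = {}  # term -> [n_pos, n_neg, n_neu]
    idx = {"positive": 0, "negative": 1, "neutral": 2}
    for ann in annotations:
        ann.validate()
        tokens = pre.transform_text(ann.text)
        for term in _sentence_terms(tokens, ngram_orders, once_per_sentence):
            counts.setdefault(term, [0, 0, 0])[idx[ann.label]] += 1
    entries: dict[str, LexiconEntry] = {}
    for term, (n_pos, n_neg, n_neu) in counts.items():
        total = n_pos + n_neg + n_neu
        if total < min_occurrences:
            continue
        entries[term] = LexiconEntry(
            score=(n_pos - n_neg) / total,
            n_pos=n_pos,
            n_neg=n_neg,
            n_neu=n_neu,
            order=len(term.split()),
        )
    return SentimentLexicon(
        entries=entries,
        ngram_orders=tuple(sorted(set(ngram_orders))),
        min_occurrences=min_occurrences,
    )


def evaluate_lexicon(
    lexicon: SentimentLexicon, truth: Mapping[str, float]
) -> tuple[float | None, float]:
    """Parameter-recovery summary against a known term → score map.

    Returns (mean absolute error over terms present in both, coverage =
    |recovered ∩ planted| / |planted|).  MAE is None when no planted term
    was recovered.
    """
    if not truth:
        raise ValueError("empty ground-truth lexicon")
    common = [t for t in truth if t in lexicon]
    coverage = len(common) / len(truth)
    if not common:
        return None, 0.0
    mae = sum(abs(lexicon.score(t) - truth[t]) for t in common) / len(common)
    if math.isnan(mae):
        raise ValueError("NaN in lexicon scores")
    return mae, coverage
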
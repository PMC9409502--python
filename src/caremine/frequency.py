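"""Unigram/bigram frequency tables, Zipf diagnostics, and the
adjacent-word sensitivity analysis.

A frequency table is an exact multiset count over one scope (all
interviews, or one speaker group).  Rank–frequency behaviour of natural
interview text is expected to be Zipf-like: log10(count) falls roughly
linearly in log10(rank), and :func:`zipf_diagnostic` reports the OLS
slope and the Pearson r of that fit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TokenizedCorpus

SCOPES = ("all", "resident", "family", "professional")


@dataclass
class FrequencyTable:
    """term → count for one scope; no zero-count entries are stored."""

    counts: Counter = field(default_factory=Counter)
    scope: str = "all"
    total_tokens: int = 0
    kind: str = "unigram"  # unigram | bigram

    def __post_init__(self):
        zero = [t for t, c in self.counts.items() if c <= 0]
        for t in zero:
            del self.counts[t]

    def __len__(self) -> int:
        return len(self.counts)

    def relative(self, term: str) -> float:
        return self.counts[term] / self.total_tokens if self.total_tokens else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: term, count, relative_frequency, scope."""
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        total = self.total_tokens or 1
        return pd.DataFrame(
            {
                "term": [t for t, _ in items],
                "count": [c for _, c in items],
                "relative_frequency": [c / total for _, c in items],
                "scope": self.scope,
            }
        )


def _check_scope(scope: str) -> None:
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def unigram_frequencies(corpus: TokenizedCorpus, scope: str = "all") -> FrequencyTable:
    """Exact unigram counts over the scope's preprocessed tokens."""
    _check_scope(scope)
    counts = Counter(corpus.flat_tokens(scope))
    return FrequencyTable(
        counts=counts,
        scope=scope,
        total_tokens=sum(counts.values()),
        kind="unigram",
    )


def bigram_frequencies(corpus: TokenizedCorpus, scope: str = "all") -> FrequencyTable:
    """Counts of consecutive token pairs, never spanning utterances.

    Each utterance of n tokens contributes max(0, n − 1) bigrams; bigram
    terms are space-joined pairs.
    """
    _check_scope(scope)
    counts: Counter = Counter()
    total = 0
    for utt in corpus.utterances_in_scope(scope, stream="bigram_tokens"):
        for a, b in zip(utt, utt[1:]):
            counts[f"{a} {b}"] += 1
        total += max(0, len(utt) - 1)
    return FrequencyTable(counts=counts, scope=scope, total_tokens=total, kind="bigram")


def top_n(table: FrequencyTable, n: int) -> list[tuple[str, int]]:
    """Top-n terms by descending count, ties broken lexicographically."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def zipf_diagnostic(table: FrequencyTable, min_count: int = 2) -> tuple[float, float]:
    """OLS fit of log10(count) on log10(rank); returns (slope, Pearson r).

    Ranks are 1-based over terms sorted by descending count (lexicographic
    tie-break).  Only ranks with count ≥ ``min_count`` enter the fit, so
    the flat hapax tail does not dominate the regression.
    """
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    pts = [
        (rank, cnt)
        for rank, (_, cnt) in enumerate(ranked, start=1)
        if cnt >= min_count
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 ranks with count >= {min_count} for a Zipf fit, got {len(pts)}"
        )
    x = np.log10([r for r, _ in pts])
    y = np.log10([c for _, c in pts])
    if np.allclose(y, y[0]):
        return 0.0, 0.0  # uniform counts: flat line, correlation undefined -> 0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue)


def adjacent_words(
    corpus: TokenizedCorpus,
    bigram: str | tuple[str, str],
    direction: str = "after",
    n: int = 10,
    scope: str = "all",
) -> list[tuple[str, int]]:
    """Words immediately following (or preceding) every occurrence of a bigram.

    Used for sensitivity analyses such as: which words follow 'heel erg'?
    Counts are within-utterance only; returns the top-n (word, count)
    pairs, descending count with lexicographic tie-break.
    """
    if direction not in ("after", "before"):
        raise ValueError("direction must be 'after' or 'before'")
    _check_scope(scope)
    if isinstance(bigram, str):
        parts = tuple(bigram.split())
        if len(parts) != 2:
            raise ValueError(f"not a bigram: {bigram!r}")
    else:
        parts = tuple(bigram)
    first, second = parts
    counts: Counter = Counter()
    for utt in corpus.utterances_in_scope(scope, stream="bigram_tokens"):
        for i in range(len(utt) - 1):
            if utt[i] == first and utt[i + 1] == second:
                if direction == "after" and i + 2 < len(utt):
                    counts[utt[i + 2]] += 1
                elif direction == "before" and i - 1 >= 0:
                    counts[utt[i - 1]] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]
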
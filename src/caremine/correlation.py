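"""Cross-group word-usage correlation.

Two speaker groups are compared by aligning their unigram frequency
tables on the union vocabulary, add-k smoothing the counts (words absent
from one group are informative, and log of zero must be avoided),
converting to relative frequencies, and correlating the log10 relative
frequencies with Pearson's r.  Words far from the diagonal in
(log fA, log fB) space are the ones the two groups use most differently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frequency import FrequencyTable


@dataclass
class GroupFrequencyPair:
    """Aligned per-term relative frequencies for two scopes."""

    terms: list[str]
    freq_a: np.ndarray
    freq_b: np.ndarray
    scope_a: str
    scope_b: str
    smoothing: float

    def __post_init__(self):
        if len(self.terms) != len(self.freq_a) or len(self.terms) != len(self.freq_b):
            raise ValueError("term and frequency vectors must align")
        if np.any(self.freq_a < 0) or np.any(self.freq_b < 0):
            raise ValueError("frequencies must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        logd = np.log10(self.freq_a) - np.log10(self.freq_b)
        return pd.DataFrame(
            {
                "term": self.terms,
                f"freq_{self.scope_a}": self.freq_a,
                f"freq_{self.scope_b}": self.freq_b,
                "log10_distance": np.abs(logd),
                "favors": np.where(logd > 0, self.scope_a, np.where(logd < 0, self.scope_b, "tie")),
            }
        )


def align_frequencies(
    table_a: FrequencyTable,
    table_b: FrequencyTable,
    smoothing: float = 1.0,
    intersection_only: bool = False,
) -> GroupFrequencyPair:
    """Align two tables on a common vocabulary with add-k smoothing.

    The term universe is the union of both vocabularies (default) or the
    intersection.  Counts get +k, then each vector is normalized by
    (total + k·V) so entries are smoothed relative frequencies.
    """
    if smoothing < 0 or (smoothing == 0 and not intersection_only):
        raise ValueError("smoothing must be > 0 in union mode, >= 0 otherwise")
    if intersection_only:
        terms = sorted(set(table_a.counts) & set(table_b.counts))
    else:
        terms = sorted(set(table_a.counts) | set(table_b.counts))
    k = smoothing
    v = len(terms)
    denom_a = table_a.total_tokens + k * v
    denom_b = table_b.total_tokens + k * v
    if denom_a == 0 or denom_b == 0:
        raise ValueError("cannot align empty, unsmoothed tables")
    fa = np.array([(table_a.counts.get(t, 0) + k) / denom_a for t in terms])
    fb = np.array([(table_b.counts.get(t, 0) + k) / denom_b for t in terms])
    return GroupFrequencyPair(
        terms=terms,
        freq_a=fa,
        freq_b=fb,
        scope_a=table_a.scope,
        scope_b=table_b.scope,
        smoothing=k,
    )


def log_pearson(pair: GroupFrequencyPair) -> float:
    """Pearson r of log10 relative frequencies across the aligned terms.

    Raises on degenerate input (fewer than 3 terms, or zero variance in
    either log-frequency vector) rather than returning NaN.
    """
    if len(pair.terms) < 3:
        raise ValueError(f"need >= 3 aligned terms, got {len(pair.terms)}")
    if np.any(pair.freq_a <= 0) or np.any(pair.freq_b <= 0):
        raise ValueError("log correlation requires strictly positive frequencies")
    la = np.log10(pair.freq_a)
    lb = np.log10(pair.freq_b)
    if np.isclose(la.std(), 0) or np.isclose(lb.std(), 0):
        raise ValueError("zero variance in log frequencies; r is undefined")
    return float(np.corrcoef(la, lb)[0, 1])


def divergent_words(pair: GroupFrequencyPair, n: int = 20) -> pd.DataFrame:
    """Top-n terms by |log10 fA − log10 fB|, annotated with the favored group.

    These are the off-diagonal words in the correlation scatter — the
    vocabulary one group uses disproportionately often.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    frame = pair.to_frame()
    frame = frame.sort_values(
        ["log10_distance", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame.head(n)


def pairwise_group_correlations(
    tables: dict[str, FrequencyTable], smoothing: float = 1.0
) -> dict[str, float]:
    """All bilateral Pearson r values between the given scopes' tables."""
    out: dict[str, float] = {}
    names = sorted(tables)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair = align_frequencies(tables[a], tables[b], smoothing=smoothing)
            out[f"{a}~{b}"] = log_pearson(pair)
    return out
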
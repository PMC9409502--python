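"""Utterance preprocessing: interviewer removal, tokenization, stop-word and
minimum-length filtering, and conservative Dutch suffix stemming.

The pipeline mirrors the conventional cleanup chain for transcribed
interview text: (1) drop everything the interviewer said, (2) lower-case
and split on non-letter characters, (3) remove the 100 most common Dutch
stop words, (4) drop tokens shorter than three characters (two-letter
Dutch words are almost always function words), and (5) reduce plurals and
diminutives to their root with ordered suffix rules.  The stemmer is
deliberately conservative: it groups inflectional variants of the same
noun, never semantically related but morphologically distinct words.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .io import Utterance

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

_VOWELS = set("aeiouáéíóúàèìòùäëïöü")


def load_default_stopwords() -> frozenset[str]:
    """The packaged list of the 100 most common Dutch stop words."""
    text = (
        resources.files("caremine.data").joinpath("stopwords_nl.txt").read_text("utf-8")
    )
    words = tuple(w for w in text.splitlines() if w.strip())
    return frozenset(words)


def filter_interviewer(utterances: Iterable[Utterance]) -> list[Utterance]:
    """Drop interviewer turns; interviewee turns pass through unchanged."""
    return [u for u in utterances if u.speaker != "interviewer"]


def tokenize(text: str) -> list[str]:
    """Lower-case and split on non-letter characters.

    Digits and punctuation are dropped, hyphenated compounds are split,
    and diacritics are preserved (input is NFC-normalized first so that
    combining marks stay attached to their letters).
    """
    return _WORD_RE.findall(unicodedata.normalize("NFC", text).lower())


def remove_stopwords(
    tokens: Sequence[str], stopwords: frozenset[str] | set[str]
) -> list[str]:
    return [t for t in tokens if t not in stopwords]


def filter_min_length(tokens: Sequence[str], min_word_length: int) -> list[str]:
    return [t for t in tokens if len(t) >= min_word_length]


class DutchSuffixStemmer:
    """Rule-based Dutch stemmer restricted to plurals and diminutives.

    Ordered suffix rules (diminutives before plurals, longest first):

    * diminutive plural ``-etjes -kjes -pjes -tjes -jes`` → stripped
    * diminutive ``-etje -kje -pje -tje -je`` → stripped
    * ``-igen`` → ``-ige`` (adjectival nouns: verpleegkundigen → verpleegkundige)
    * plural ``-en`` → stripped, then a doubled final consonant is
      undoubled (mannen → man) and final v/z revert to f/s
      (duiven → duif, huizen → huis)
    * plural ``-s`` → stripped when preceded by a consonant (tafels →
      tafel) but kept after a vowel (huis stays huis)

    A rule only applies when it leaves at least ``min_stem`` characters.
    Rules are re-applied until no rule matches, so the result is always a
    fixed point of the stemmer (idempotence by construction).
    """

    _DIMINUTIVES = ("etjes", "kjes", "pjes", "tjes", "jes", "etje", "kje", "pje", "tje", "je")

    def __init__(self, min_stem: int = 3):
        if min_stem < 1:
            raise ValueError("min_stem must be >= 1")
        self.min_stem = min_stem

    def __call__(self, token: str) -> str:
        current = token
        while True:
            nxt = self._step(current)
            if nxt == current:
                return current
            current = nxt

    def _step(self, w: str) -> str:
        n = self.min_stem
        if w.endswith("'s") and len(w) - 2 >= n:
            return w[:-2]
        for suf in self._DIMINUTIVES:
            if w.endswith(suf) and len(w) - len(suf) >= n:
                return w[: -len(suf)]
        if w.endswith("igen") and len(w) - 1 >= n:
            return w[:-1]
        if w.endswith("en") and len(w) - 2 >= n:
            stem = w[:-2]
            if (
                len(stem) >= 2
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
            ):
                stem = stem[:-1]
            elif stem.endswith("v"):
                stem = stem[:-1] + "f"
            elif stem.endswith("z"):
                stem = stem[:-1] + "s"
            if len(stem) >= n:
                return stem
            return w
        if (
            w.endswith("s")
            and not w.endswith("ss")
            and len(w) - 1 >= n
            and len(w) >= 2
            and w[-2] not in _VOWELS
        ):
            return w[:-1]
        return w


_default_stemmer = DutchSuffixStemmer()


def stem(token: str) -> str:
    """Stem one token with the default Dutch plural/diminutive rules."""
    return _default_stemmer(token)


@dataclass
class TokenizedCorpus:
    """Per-interview token streams after preprocessing (interviewee only).

    ``tokens`` holds the fully preprocessed stream (stop words removed);
    ``bigram_tokens`` holds the stream used for bigram counting, which by
    default keeps stop words (high-frequency bigrams like 'heel erg' are
    informative) but applies the length filter and stemming.  Utterance
    boundaries are preserved in both streams so n-grams never span turns.
    """

    tokens: dict[str, list[list[str]]] = field(default_factory=dict)
    bigram_tokens: dict[str, list[list[str]]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[int]] = field(default_factory=dict)

    def interview_ids(self, scope: str = "all") -> list[str]:
        return [
            iid
            for iid in self.tokens
            if scope == "all" or self.groups[iid] == scope
        ]

    def utterances_in_scope(
        self, scope: str = "all", stream: str = "tokens"
    ) -> list[list[str]]:
        source = self.tokens if stream == "tokens" else self.bigram_tokens
        return [
            utt for iid in self.interview_ids(scope) for utt in source[iid]
        ]

    def flat_tokens(self, scope: str = "all") -> list[str]:
        return [t for utt in self.utterances_in_scope(scope) for t in utt]

    def n_tokens(self, scope: str = "all") -> int:
        return sum(len(u) for u in self.utterances_in_scope(scope))


class DutchPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer from raw utterances to a :class:`TokenizedCorpus`.

    Parameters
    ----------
    stopwords : frozenset of str, optional
        Stop-word list matched on raw lower-cased tokens; defaults to the
        packaged 100-entry Dutch list.
    min_word_length : int, default 3
        Minimum token length in characters.
    stemming_enabled : bool, default True
        Apply the plural/diminutive suffix stemmer.
    bigram_keep_stopwords : bool, default True
        Keep stop words in the stream used for bigram counting.
    stemmer : callable, optional
        Alternative token → stem mapping (adapter hook for a full Dutch
        stemmer); defaults to :class:`DutchSuffixStemmer`.
    """

    def __init__(
        self,
        stopwords: frozenset[str] | None = None,
        min_word_length: int = 3,
        stemming_enabled: bool = True,
        bigram_keep_stopwords: bool = True,
        stemmer: Callable[[str], str] | None = None,
    ):
        self.stopwords = stopwords
        self.min_word_length = min_word_length
        self.stemming_enabled = stemming_enabled
        self.bigram_keep_stopwords = bigram_keep_stopwords
        self.stemmer = stemmer

    def fit(self, X=None, y=None):  # stateless; sklearn API compliance
        if self.min_word_length < 1:
            raise ValueError("min_word_length must be >= 1")
        return self

    def _resolved(self):
        stops = (
            self.stopwords
            if self.stopwords is not None
            else load_default_stopwords()
        )
        stemmer = self.stemmer if self.stemmer is not None else _default_stemmer
        return frozenset(stops), stemmer

    def transform_text(self, text: str) -> list[str]:
        """Preprocess one bare sentence: tokenize, stop words, length, stem."""
        self.fit()
        stops, stemmer = self._resolved()
        toks = filter_min_length(
            remove_stopwords(tokenize(text), stops), self.min_word_length
        )
        return [stemmer(t) for t in toks] if self.stemming_enabled else toks

    def transform(self, X: Iterable[Utterance]) -> TokenizedCorpus:
        self.fit()
        stops, stemmer = self._resolved()
        corpus = TokenizedCorpus()
        # canonical order, so input permutation cannot change any stream
        utterances = sorted(X, key=lambda u: (u.interview_id, u.position))
        kept = filter_interviewer(utterances)
        # Register every interview (and its group) even if all its turns
        # were the interviewer's: downstream stages must see it as empty.
        seen_groups: dict[str, str] = {}
        for u in utterances:
            seen_groups.setdefault(u.interview_id, u.group)
        for iid, grp in seen_groups.items():
            corpus.tokens[iid] = []
            corpus.bigram_tokens[iid] = []
            corpus.groups[iid] = grp
            corpus.provenance[iid] = []
        n_raw = n_stopped = n_len = 0
        for u in kept:
            raw = tokenize(u.text)
            n_raw += len(raw)
            unstopped = remove_stopwords(raw, stops)
            n_stopped += len(unstopped)
            sized = filter_min_length(unstopped, self.min_word_length)
            n_len += len(sized)
            stemmed = (
                [stemmer(t) for t in sized] if self.stemming_enabled else sized
            )
            bigram_base = (
                filter_min_length(raw, self.min_word_length)
                if self.bigram_keep_stopwords
                else sized
            )
            bigram_stream = (
                [stemmer(t) for t in bigram_base]
                if self.stemming_enabled
                else bigram_base
            )
            corpus.tokens[u.interview_id].append(stemmed)
            corpus.bigram_tokens[u.interview_id].append(bigram_stream)
            corpus.provenance[u.interview_id].append(u.position)
        logger.info(
            "preprocess: %d raw tokens -> %d after stop words -> %d after "
            "length filter (%d interviews)",
            n_raw,
            n_stopped,
            n_len,
            len(corpus.tokens),
        )
        for iid in corpus.tokens:
            logger.debug(
                "preprocess: interview %s: %d tokens",
                iid,
                sum(len(t) for t in corpus.tokens[iid]),
            )
        return corpus


def preprocess_pipeline(
    utterances: Iterable[Utterance], config: DutchPreprocessor | None = None
) -> TokenizedCorpus:
    """Apply the five-step preprocessing chain and return the token streams."""
    pre = config if config is not None else DutchPreprocessor()
    return pre.transform(list(utterances))
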
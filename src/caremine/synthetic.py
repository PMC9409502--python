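"""Synthetic interview corpus and annotation-survey generator.

The study conditions emulated here are triadic nursing-home interviews:
three speaker groups (39 resident, 37 family, 49 care-professional
interviews — 125 in total), with interviewer and interviewee turns, where
residents speak least and care professionals most (≈285 / 362 / 549
interviewee words per interview).  Token frequencies follow a Zipf
rank–frequency law; the 100 packaged Dutch stop words occupy the top
ranks.  On top of the Zipfian background the generator plants structure
with a recoverable ground truth:

* **topics** — each interviewee utterance is assigned one topic; a fixed
  share of its tokens is drawn from that topic's keyword list, so topic
  keywords co-occur within utterances and are distributionally separable;
* **sentiment** — a planted lexicon of evaluative terms with true scores
  in [−1, 1]; each interview has a latent sentiment bias (group means and
  spreads differ, making care professionals the most dispersed group) that
  tilts which sentiment terms it uses;
* **group tilt** — optionally, each group over-uses a private subset of
  background words, creating the off-diagonal words of cross-group
  correlation scatters;
* **morphology** — content tokens surface in plural or diminutive form at
  a configurable rate, using only suffixes the packaged stemmer provably
  inverts, so preprocessing recovers the planted stems exactly.

Generated text is token salad, not grammatical Dutch: it reproduces the
distributional properties the pipeline consumes, nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AnnotatedSentence, Utterance
from .preprocess import DutchPreprocessor, load_default_stopwords, stem

SENTIMENT_THRESHOLD = 0.1  # ternary band half-width shared with the scorer


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# pseudo-word construction

_ONSETS = (
    "b", "d", "f", "g", "h", "k", "l", "m", "n", "p", "r", "t", "v", "w", "z",
    "st", "sl", "kr", "br", "gr", "sch", "zw", "pl", "kl", "vr", "sp", "dr",
)
_NUCLEI = ("a", "e", "i", "o", "u", "aa", "ee", "oo", "oe", "ei", "ui", "ie", "au")
_CODAS = ("", "k", "t", "n", "l", "r", "m", "p", "g", "f", "rt", "st", "lk", "ng", "nk")


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    parts = []
    for _ in range(n_syll):
        parts.append(str(rng.choice(_ONSETS)))
        parts.append(str(rng.choice(_NUCLEI)))
        parts.append(str(rng.choice(_CODAS)))
    return "".join(parts)


def make_pseudo_words(
    n: int, rng: np.random.Generator, forbidden: set[str] | None = None
) -> list[str]:
    """Generate ``n`` distinct stem-canonical pseudo-Dutch content words."""
    forbidden = set(forbidden or ())
    out: list[str] = []
    seen = set(forbidden)
    while len(out) < n:
        w = stem(_pseudo_word(rng))
        if len(w) < 3 or w in seen:
            continue
        seen.add(w)
        out.append(w)
    return out


_SAFE_SUFFIXES = ("s", "en", "je", "tje", "jes")


def safe_inflections(word: str) -> list[str]:
    """Surface variants of ``word`` that the stemmer provably maps back."""
    return [word + s for s in _SAFE_SUFFIXES if stem(word + s) == word]


# ---------------------------------------------------------------------------
# configuration and ground truth

#: Table-style default topic mix: 12 themes with weights proportional to
#: their prominence in long-term-care narratives (relations, time and life
#: experiences dominate; health and food are small, well-separated themes).
_DEFAULT_TOPIC_WEIGHTS = {
    "relations": 1995,
    "activities": 996,
    "time": 2175,
    "care_organization": 1072,
    "daily_experiences": 525,
    "physical_environment": 1106,
    "health": 423,
    "food": 527,
    "life_experiences": 1827,
    "care_environment": 1432,
    "physical_appearance": 860,
    "miscellaneous": 868,
}


def default_topic_spec(
    n_keywords: int = 8, seed: int = 20220825
) -> list[tuple[str, list[str], float]]:
    """Default planted topics: 12 themes, ``n_keywords`` pseudo-words each."""
    rng = np.random.default_rng(seed)
    total = sum(_DEFAULT_TOPIC_WEIGHTS.values())
    words = make_pseudo_words(
        n_keywords * len(_DEFAULT_TOPIC_WEIGHTS), rng, forbidden=set(load_default_stopwords())
    )
    spec = []
    for i, (label, w) in enumerate(_DEFAULT_TOPIC_WEIGHTS.items()):
        spec.append(
            (label, words[i * n_keywords : (i + 1) * n_keywords], w / total)
        )
    return spec


@dataclass
class CorpusConfig:
    """Study-scale defaults: 39/37/49 interviews uttering ≈285/362/549
    interviewee words each, a 2000-stem vocabulary with Zipf exponent 1,
    12 planted topics, and a 60-term planted sentiment lexicon."""

    n_interviews_per_group: dict[str, int] = field(
        default_factory=lambda: {"resident": 39, "family": 37, "professional": 49}
    )
    mean_words_per_interview: dict[str, float] = field(
        default_factory=lambda: {
            "resident": 284.9,
            "family": 362.1,
            "professional": 548.7,
        }
    )
    vocab_size: int = 2000
    zipf_exponent: float = 1.0
    topic_spec: list[tuple[str, list[str], float]] | None = None
    interviewer_fraction: float = 0.3
    seed: int = 0
    # structure shares and shape parameters
    topic_token_share: float = 0.25
    n_sentiment_terms: int = 60
    sentiment_token_share: float = 0.12
    mean_utterance_words: float = 12.0
    nb_dispersion: float = 20.0
    inflection_rate: float = 0.25
    # per-group sentiment regime: residents homogeneous and balanced,
    # family slightly negative, professionals positive and most diverse
    group_sentiment_bias: dict[str, float] = field(
        default_factory=lambda: {"resident": 0.0, "family": -0.15, "professional": 0.15}
    )
    group_sentiment_spread: dict[str, float] = field(
        default_factory=lambda: {"resident": 0.15, "family": 0.35, "professional": 0.7}
    )
    # cross-group word-usage tilt (0 = identical vocabularies)
    group_tilt: float = 0.0
    n_tilted_terms: int = 50

    def resolved_topic_spec(self) -> list[tuple[str, list[str], float]]:
        return self.topic_spec if self.topic_spec is not None else default_topic_spec()

    def validate(self) -> None:
        for g, n in self.n_interviews_per_group.items():
            if n < 0:
                raise ConfigError(f"negative interview count for {g!r}: {n}")
            if g not in ("resident", "family", "professional"):
                raise ConfigError(f"unknown group {g!r}")
        for g in self.n_interviews_per_group:
            if self.mean_words_per_interview.get(g, 0) <= 0:
                raise ConfigError(f"mean_words_per_interview for {g!r} must be > 0")
        if self.vocab_size <= 0:
            raise ConfigError("vocab_size must be positive")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        if not 0 <= self.interviewer_fraction < 1:
            raise ConfigError("interviewer_fraction must be in [0, 1)")
        spec = self.resolved_topic_spec()
        if spec:
            wsum = sum(w for _, _, w in spec)
            if abs(wsum - 1.0) > 1e-9:
                raise ConfigError(f"topic mixing weights sum to {wsum}, not 1")
            if any(not kws for _, kws, _ in spec):
                raise ConfigError("every topic needs at least one keyword")
        all_kw = [k for _, kws, _ in spec for k in kws]
        if len(set(all_kw)) != len(all_kw):
            raise ConfigError("planted keywords must be unique across topics")
        n_struct = len(all_kw) + self.n_sentiment_terms
        if self.vocab_size < n_struct:
            raise ConfigError(
                f"vocab_size {self.vocab_size} < {n_struct} planted terms"
            )
        if not 0 <= self.topic_token_share + self.sentiment_token_share < 1:
            raise ConfigError("token shares must leave room for background text")


@dataclass
class GroundTruth:
    """Everything needed to verify downstream recovery on one corpus."""

    planted_lexicon: dict[str, float] = field(default_factory=dict)
    topic_assignment: dict[str, str] = field(default_factory=dict)
    interview_ternary: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    group_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    pos_tags: dict[str, str] = field(default_factory=dict)
    interview_bias: dict[str, float] = field(default_factory=dict)
    tilted_terms: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "planted_lexicon": self.planted_lexicon,
                    "topic_assignment": self.topic_assignment,
                    "interview_ternary": self.interview_ternary,
                    "group_profiles": self.group_profiles,
                    "pos_tags": self.pos_tags,
                    "interview_bias": self.interview_bias,
                    "tilted_terms": self.tilted_terms,
                },
                fh,
                ensure_ascii=False,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            planted_lexicon=d["planted_lexicon"],
            topic_assignment=d["topic_assignment"],
            interview_ternary={k: tuple(v) for k, v in d["interview_ternary"].items()},
            group_profiles=d["group_profiles"],
            pos_tags=d["pos_tags"],
            interview_bias=d["interview_bias"],
            tilted_terms=d["tilted_terms"],
        )


# ---------------------------------------------------------------------------
# corpus generation


def _draw(cum: np.ndarray, r):
    """Inverse-CDF draw(s); clipped so float round-off in the last bin
    cannot index out of range."""
    return np.minimum(np.searchsorted(cum, r), len(cum) - 1)


def _true_label(stems: Sequence[str], lexicon: dict[str, float]) -> str:
    """The generator's labeling rule: mean planted score over matched
    terms, thresholded at ±0.1; no matches means neutral."""
    scores = [lexicon[t] for t in stems if t in lexicon]
    if not scores:
        return "neutral"
    m = sum(scores) / len(scores)
    if m > SENTIMENT_THRESHOLD:
        return "positive"
    if m < -SENTIMENT_THRESHOLD:
        return "negative"
    return "neutral"


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[Utterance], GroundTruth]:
    """Generate a transcript set with known structure; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stopwords = sorted(load_default_stopwords())
    spec = config.resolved_topic_spec()
    keywords = [k for _, kws, _ in spec for k in kws]
    for k in keywords:
        if stem(k) != k:
            raise ConfigError(f"planted keyword {k!r} is not stem-canonical")

    n_background = config.vocab_size - len(keywords) - config.n_sentiment_terms
    n_bg_content = max(0, n_background - len(stopwords))
    forbidden = set(stopwords) | set(keywords)
    content = make_pseudo_words(
        n_bg_content + config.n_sentiment_terms, rng, forbidden=forbidden
    )
    bg_content, sent_terms = content[:n_bg_content], content[n_bg_content:]

    # Zipfian background: stop words occupy the top ranks.
    bg_vocab = np.array(stopwords + bg_content)
    ranks = np.arange(1, len(bg_vocab) + 1, dtype=float)
    base_w = ranks ** (-config.zipf_exponent)

    truth = GroundTruth()
    for label, kws, _ in spec:
        for k in kws:
            truth.topic_assignment[k] = label

    # planted sentiment scores: spread over [-1, 1] with both extremes present
    if sent_terms:
        scores = np.linspace(-1.0, 1.0, len(sent_terms))
        order = rng.permutation(len(sent_terms))
        truth.planted_lexicon = {
            sent_terms[i]: float(scores[order[i]]) for i in range(len(sent_terms))
        }

    # POS ground truth: keywords are nouns by construction; a share of the
    # background content vocabulary is nominal too; planted sentiment terms
    # behave like evaluative adjectives.
    for k in keywords:
        truth.pos_tags[k] = "NOUN"
    for w in bg_content:
        truth.pos_tags[w] = "NOUN" if rng.random() < 0.35 else "X"
    for t in sent_terms:
        truth.pos_tags[t] = "ADJ"
    for s in stopwords:
        truth.pos_tags[s] = "X"

    groups = sorted(config.n_interviews_per_group)
    # per-group background distributions (optionally tilted)
    tilt_pool = rng.permutation(len(bg_content))
    group_bg: dict[str, np.ndarray] = {}
    for gi, g in enumerate(groups):
        w = base_w.copy()
        if config.group_tilt > 0 and config.n_tilted_terms > 0:
            lo = gi * config.n_tilted_terms
            idx = tilt_pool[lo : lo + config.n_tilted_terms]
            w[len(stopwords) + idx] *= 1.0 + config.group_tilt
            truth.tilted_terms[g] = [bg_content[j] for j in idx]
        group_bg[g] = w / w.sum()
        truth.group_profiles[g] = {
            str(bg_vocab[j]): float(group_bg[g][j]) for j in range(len(bg_vocab))
        }

    topic_weights = np.array([w for _, _, w in spec]) if spec else None
    topic_kw_arrays = [np.array(kws) for _, kws, _ in spec]
    sent_arr = np.array(sent_terms) if sent_terms else None
    sent_scores = (
        np.array([truth.planted_lexicon[t] for t in sent_terms]) if sent_terms else None
    )

    interviewer_mean = (
        config.mean_utterance_words
        * config.interviewer_fraction
        / (1.0 - config.interviewer_fraction)
    )

    utterances: list[Utterance] = []
    inflection_cache: dict[str, list[str]] = {}

    def surface(stem_tok: str) -> str:
        if stem_tok in stopwords_set or config.inflection_rate <= 0:
            return stem_tok
        if rng.random() >= config.inflection_rate:
            return stem_tok
        variants = inflection_cache.get(stem_tok)
        if variants is None:
            variants = safe_inflections(stem_tok)
            inflection_cache[stem_tok] = variants
        if not variants:
            return stem_tok
        return variants[int(rng.integers(len(variants)))]

    stopwords_set = set(stopwords)

    group_bg_cum = {g: np.cumsum(w) for g, w in group_bg.items()}
    topic_cum = np.cumsum(topic_weights) if spec else None

    for g in groups:
        n_int = config.n_interviews_per_group[g]
        m_words = config.mean_words_per_interview.get(g, 0.0)
        bg_cum = group_bg_cum[g]
        for k in range(n_int):
            iid = f"{g[:3]}-{k + 1:03d}"
            bias = float(
                np.clip(
                    rng.normal(
                        config.group_sentiment_bias.get(g, 0.0),
                        config.group_sentiment_spread.get(g, 0.0),
                    ),
                    -1.0,
                    1.0,
                )
            )
            truth.interview_bias[iid] = bias
            if sent_arr is not None:
                sw = np.exp(2.0 * bias * sent_scores)
                sent_cum = np.cumsum(sw / sw.sum())
            size = config.nb_dispersion
            total_words = int(
                rng.negative_binomial(size, size / (size + m_words))
            )
            n_utt = max(1, round(total_words / config.mean_utterance_words))
            position = 0
            n_pos = n_neg = 0
            for _ in range(n_utt):
                li = int(rng.poisson(interviewer_mean))
                if li > 0:
                    idx = _draw(bg_cum, rng.random(li))
                    text = (
                        " ".join(surface(str(bg_vocab[j])) for j in idx).capitalize()
                        + "?"
                    )
                    utterances.append(
                        Utterance(iid, g, "interviewer", position, text)
                    )
                    position += 1
                lw = 1 + int(rng.poisson(max(config.mean_utterance_words - 1, 0)))
                topic_i = (
                    int(_draw(topic_cum, rng.random())) if spec else -1
                )
                u = rng.random(lw)
                stems: list[str] = [""] * lw
                topic_mask = (
                    u < config.topic_token_share
                    if spec
                    else np.zeros(lw, dtype=bool)
                )
                sent_mask = (
                    (~topic_mask)
                    & (u < config.topic_token_share + config.sentiment_token_share)
                    if sent_arr is not None
                    else np.zeros(lw, dtype=bool)
                )
                bg_mask = ~(topic_mask | sent_mask)
                if topic_mask.any():
                    kw = topic_kw_arrays[topic_i]
                    draws = rng.integers(len(kw), size=int(topic_mask.sum()))
                    for j, d in zip(np.flatnonzero(topic_mask), draws):
                        stems[j] = str(kw[d])
                if sent_mask.any():
                    draws = _draw(sent_cum, rng.random(int(sent_mask.sum())))
                    for j, d in zip(np.flatnonzero(sent_mask), draws):
                        stems[j] = str(sent_arr[d])
                if bg_mask.any():
                    draws = _draw(bg_cum, rng.random(int(bg_mask.sum())))
                    for j, d in zip(np.flatnonzero(bg_mask), draws):
                        stems[j] = str(bg_vocab[d])
                label = _true_label(stems, truth.planted_lexicon)
                n_pos += label == "positive"
                n_neg += label == "negative"
                text = " ".join(surface(t) for t in stems).capitalize() + "."
                utterances.append(Utterance(iid, g, "interviewee", position, text))
                position += 1
            pct_pos = 100.0 * n_pos / n_utt
            pct_neg = 100.0 * n_neg / n_utt
            # complement of (pos + neg), so pos + neg + neu == 100 exactly
            truth.interview_ternary[iid] = (
                pct_pos,
                pct_neg,
                100.0 - (pct_pos + pct_neg),
            )
    return utterances, truth


# ---------------------------------------------------------------------------
# survey generation


def generate_survey(
    utterances: Sequence[Utterance],
    lexicon: dict[str, float],
    n_sentences: int,
    n_annotators: int,
    label_noise: float = 0.0,
    seed: int = 0,
    annotators_per_sentence: int = 1,
    preprocessor: DutchPreprocessor | None = None,
) -> list[AnnotatedSentence]:
    """Sample interviewee utterances and label them like survey annotators.

    Each sampled sentence receives one judgement from each of
    ``annotators_per_sentence`` distinct annotators.  The noise-free label
    is the generator's thresholding rule applied to the sentence's planted
    term scores; with probability ``label_noise`` an annotator reports one
    of the other two labels instead (chosen uniformly).
    """
    for t, s in lexicon.items():
        if not -1.0 <= s <= 1.0:
            raise ConfigError(f"planted score for {t!r} outside [-1, 1]")
    if not 0 <= label_noise < 0.5:
        raise ConfigError(f"label_noise must be in [0, 0.5), got {label_noise}")
    if n_annotators < annotators_per_sentence:
        raise ConfigError("annotator pool smaller than annotators per sentence")
    pool = [u for u in utterances if u.speaker == "interviewee"]
    if n_sentences > len(pool):
        raise ConfigError(
            f"requested {n_sentences} sentences but only {len(pool)} "
            f"interviewee utterances are available (short by {n_sentences - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    pre = preprocessor if preprocessor is not None else DutchPreprocessor()

    ages = np.clip(np.round(rng.normal(41.0, 13.7, size=n_annotators)), 18, 90)
    genders = rng.choice(["female", "male"], size=n_annotators, p=[0.71, 0.29])
    educations = rng.choice(
        ["master", "bachelor", "other"], size=n_annotators, p=[0.67, 0.21, 0.12]
    )
    regions = rng.choice(["south", "other"], size=n_annotators, p=[0.67, 0.33])

    labels = ("positive", "neutral", "negative")
    chosen = rng.choice(len(pool), size=n_sentences, replace=False)
    out: list[AnnotatedSentence] = []
    for si in chosen:
        u = pool[int(si)]
        stems = pre.transform_text(u.text)
        true = _true_label(stems, lexicon)
        annotators = rng.choice(n_annotators, size=annotators_per_sentence, replace=False)
        for ai in annotators:
            ai = int(ai)
            lab = true
            if label_noise > 0 and rng.random() < label_noise:
                others = [l for l in labels if l != true]
                lab = others[int(rng.integers(2))]
            out.append(
                AnnotatedSentence(
                    sentence_id=f"{u.interview_id}:{u.position}",
                    text=u.text,
                    label=lab,
                    annotator_id=f"a{ai:04d}",
                    age=str(int(ages[ai])),
                    gender=str(genders[ai]),
                    education=str(educations[ai]),
                    region=str(regions[ai]),
                )
            )
    return out
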
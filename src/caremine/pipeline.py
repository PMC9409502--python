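"""End-to-end orchestration: one config, six stages, reproducible outputs.

Every output table carries a ``# key=value`` metadata header (seed,
config hash, tool version) and the run writes a manifest, so a run is
fully identified by its inputs and seed.  The global seed fans out to
per-stage seeds through a stable hash of the stage name, making each
stage independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .correlation import align_frequencies, divergent_words, log_pearson
from .frequency import bigram_frequencies, unigram_frequencies, zipf_diagnostic
from .io import (
    load_annotations,
    load_transcripts,
    write_annotations,
    write_json,
    write_table,
    write_transcripts,
)
from .lexicon import build_lexicon
from .preprocess import DutchPreprocessor
from .sentiment import group_dispersion, interview_ternary, ternary_frame, word_sentiment_scatter
from .synthetic import CorpusConfig, generate_corpus, generate_survey
from .topics import HeuristicDutchNounTagger, KeywordTopicModel, LexiconPOSTagger

logger = logging.getLogger(__name__)

GROUP_SCOPES = ("resident", "family", "professional")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    transcripts: str = "transcripts.jsonl"
    annotations: str = "annotations.tsv"
    out_dir: str = "caremine_out"
    pos_tags: str | None = None  # optional JSON file: token -> POS tag
    # preprocessing
    min_word_length: int = 3
    stemming_enabled: bool = True
    bigram_keep_stopwords: bool = True
    # lexicon
    min_occurrences: int = 3
    ngram_orders: tuple[int, ...] = (1, 2)
    # sentiment
    tau: float = 0.1
    aggregate: str = "mean"
    # topics
    embedding_dim: int = 50
    window: int = 5
    min_count: int = 3
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 20)
    restarts: int = 10
    # reporting
    top_n: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ngram_orders", "k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def metadata(self) -> dict:
        return {
            "tool": f"caremine {__version__}",
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }

    def preprocessor(self) -> DutchPreprocessor:
        return DutchPreprocessor(
            min_word_length=self.min_word_length,
            stemming_enabled=self.stemming_enabled,
            bigram_keep_stopwords=self.bigram_keep_stopwords,
        )


@dataclass
class SimulateConfig:
    """Synthetic-dataset generation settings (study-scale defaults)."""

    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    out_dir: str = "caremine_data"
    survey_coverage: float = 0.56  # fraction of interviewee utterances annotated
    n_annotators: int = 234
    annotators_per_sentence: int = 3
    label_noise: float = 0.1


def simulate(config: SimulateConfig) -> dict:
    """Generate and write transcripts.jsonl, annotations.tsv, ground_truth.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    utterances, truth = generate_corpus(config.corpus)
    n_interviewee = sum(1 for u in utterances if u.speaker == "interviewee")
    n_sentences = int(round(config.survey_coverage * n_interviewee))
    survey = generate_survey(
        utterances,
        truth.planted_lexicon,
        n_sentences=n_sentences,
        n_annotators=config.n_annotators,
        label_noise=config.label_noise,
        seed=derive_seed(config.corpus.seed, "survey"),
        annotators_per_sentence=config.annotators_per_sentence,
    )
    meta = {"tool": f"caremine {__version__}", "seed": config.corpus.seed}
    write_transcripts(utterances, out / "transcripts.jsonl", metadata=meta)
    write_annotations(survey, out / "annotations.tsv", metadata=meta)
    truth.to_json(out / "ground_truth.json")
    n_interviews = len({u.interview_id for u in utterances})
    logger.info(
        "simulate: %d interviews, %d utterances, %d annotations -> %s",
        n_interviews,
        len(utterances),
        len(survey),
        out,
    )
    return {
        "n_interviews": n_interviews,
        "n_utterances": len(utterances),
        "n_annotations": len(survey),
        "out_dir": str(out),
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute preprocess → frequency → correlation → lexicon → sentiment
    → topics, writing all tables plus a run manifest.

    Any stage failure is re-raised as :class:`StageError` naming the
    stage.  Deterministic for fixed inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    manifest: dict = {**meta, "stages": {}}
    if not Path(config.transcripts).exists():
        raise StageError(f"config: transcripts path {config.transcripts!r} does not exist")
    if not Path(config.annotations).exists():
        raise StageError(f"config: annotations path {config.annotations!r} does not exist")

    def _run(name, fn):
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = result
        logger.info("stage %s done: %s", name, result)
        return result

    pre = config.preprocessor()

    def _preprocess():
        nonlocal corpus
        utterances = load_transcripts(config.transcripts)
        corpus = pre.transform(utterances)
        return {"n_interviews": len(corpus.tokens), "n_tokens": corpus.n_tokens()}

    corpus = None

    def _frequency():
        info = {}
        for scope in ("all",) + GROUP_SCOPES:
            uni = unigram_frequencies(corpus, scope)
            big = bigram_frequencies(corpus, scope)
            write_table(uni.to_frame().head(5000), out / f"unigrams_{scope}.tsv", meta)
            write_table(big.to_frame().head(5000), out / f"bigrams_{scope}.tsv", meta)
            if len(uni) >= 3:
                slope, r = zipf_diagnostic(uni)
                info[scope] = {"slope": slope, "r": r, "n_types": len(uni)}
        return info

    def _correlation():
        tables = {s: unigram_frequencies(corpus, s) for s in GROUP_SCOPES}
        rs = {}
        for a, b in (("resident", "family"), ("resident", "professional"), ("professional", "family")):
            pair = align_frequencies(tables[a], tables[b])
            rs[f"{a}~{b}"] = log_pearson(pair)
            write_table(divergent_words(pair, n=50), out / f"divergent_{a}_{b}.tsv", meta)
        write_json(rs, out / "correlations.json", meta)
        return rs

    def _lexicon():
        nonlocal lex
        annotations = load_annotations(config.annotations)
        lex = build_lexicon(
            annotations,
            preprocessor=pre,
            min_occurrences=config.min_occurrences,
            ngram_orders=tuple(config.ngram_orders),
        )
        write_table(lex.to_frame(), out / "lexicon.tsv", meta)
        return {"n_terms": len(lex)}

    lex = None

    def _sentiment():
        points = interview_ternary(corpus, lex, tau=config.tau, aggregate=config.aggregate)
        write_table(ternary_frame(points), out / "ternary.tsv", meta)
        disp = group_dispersion(points)
        write_json(disp, out / "dispersion.json", meta)
        for scope in GROUP_SCOPES:
            write_table(
                word_sentiment_scatter(corpus, lex, top_n=40, scope=scope),
                out / f"word_sentiment_{scope}.tsv",
                meta,
            )
        return {g: d["dispersion"] for g, d in disp.items()}

    def _topics():
        if config.pos_tags:
            with open(config.pos_tags, encoding="utf-8") as fh:
                tags = json.load(fh)
            if "pos_tags" in tags:  # accept a full ground-truth document
                tags = tags["pos_tags"]
            tagger = LexiconPOSTagger(tags)
        else:
            tagger = HeuristicDutchNounTagger()
        model = KeywordTopicModel(
            tagger=tagger,
            d=config.embedding_dim,
            window=config.window,
            min_count=config.min_count,
            k=config.k,
            k_range=tuple(config.k_range),
            restarts=config.restarts,
            random_state=derive_seed(config.seed, "topics"),
        )
        model.fit(corpus)
        report = model.report(top_m=5)
        write_table(report, out / "topic_clusters.tsv", meta)
        write_json(
            {
                "k": model.k_,
                "wss_curve": {str(k): v for k, v in model.wss_curve_.items()},
                "clusters": {
                    t: {
                        "cluster": model.assignments_[t],
                        "xy": list(model.projection_[t]),
                        "count": int(model.keywords_.counts[t]),
                    }
                    for t in model.terms_
                },
            },
            out / "topics.json",
            meta,
        )
        return {"k": model.k_, "n_keywords": len(model.terms_)}

    _run("preprocess", _preprocess)
    _run("frequency", _frequency)
    _run("correlation", _correlation)
    _run("lexicon", _lexicon)
    _run("sentiment", _sentiment)
    _run("topics", _topics)
    write_json(manifest, out / "manifest.json")
    return manifest
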
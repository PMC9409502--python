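# caremine

Text mining for narrative quality-of-care data in long-term care for
older adults. Nursing-home quality assessments increasingly rest on
narrative material — verbatim transcripts of separate interviews with
residents, their family members and care professionals (triads) — which
quickly grows beyond what manual coding can process. `caremine`
implements a transparent, lexicon-based pipeline for such corpora:

1. **Preprocessing** — interviewer turns removed; lower-cased letter-run
   tokenization; the 100 most common Dutch stop words removed; minimum
   word length 3; conservative rule-based stemming of Dutch plurals and
   diminutives (*verpleegkundigen → verpleegkundige*).
2. **Word frequencies** — exact unigram and within-utterance bigram
   tables per speaker group, top-*n* extracts, a Zipf rank–frequency
   diagnostic (OLS slope of log₁₀ count on log₁₀ rank), and an
   adjacent-word sensitivity analysis (which words follow *heel erg*?).
3. **Cross-group correlation** — for each pair of groups, Pearson *r*
   between log₁₀ relative word frequencies on the union vocabulary
   (add-1 smoothed), plus the most divergent (off-diagonal) words.
4. **Sentiment** — a domain lexicon built from a sentence-annotation
   survey by the frequency-of-context rule
   `score(w) = (n_pos − n_neg) / (n_pos + n_neg + n_neu) ∈ [−1, 1]`
   (a word seen 9× in positive and 1× in negative context scores 0.8);
   sentences score the mean of matched terms (bigram matches suppress
   their component unigrams) and are classed positive/neutral/negative
   with a ±0.1 neutral band; each interview becomes a ternary point
   (positive% + negative% + neutral% = 100) and groups are compared by
   mean pairwise dispersion of those points.
5. **Topic clustering** — noun keywords via a pluggable POS tagger,
   PPMI–SVD distributional embeddings trained on the corpus itself,
   k-means with elbow-selected k, a 2-D projection and a per-cluster
   keyword/occurrence report.

Because real transcripts of this kind cannot be shared, the package
includes a first-class **synthetic corpus generator**
(`caremine.synthetic`) that emulates the study conditions — 39/37/49
interviews with ≈285/362/549 interviewee words each, Zipfian vocabulary,
planted topics, a planted sentiment lexicon with per-group bias and
spread, and an annotation survey with configurable label noise — so
every stage can be validated against a known ground truth.

## Worked example

```python
from caremine import *

simulate(SimulateConfig(corpus=CorpusConfig(seed=7), out_dir="demo"))
# {'n_interviews': 125, 'n_utterances': 8748, 'n_annotations': 7368, ...}

corpus = DutchPreprocessor().transform(load_transcripts("demo/transcripts.jsonl"))
zipf_diagnostic(unigram_frequencies(corpus, "all"))
# (-1.12, -0.978)   # rank-frequency slope ≈ −1 and a tight log-log fit

pair = align_frequencies(unigram_frequencies(corpus, "resident"),
                         unigram_frequencies(corpus, "family"))
log_pearson(pair)
# 0.724             # residents and family use largely the same words

lex = build_lexicon(load_annotations("demo/annotations.tsv"))
points = interview_ternary(corpus, lex)
group_dispersion(points)["professional"]["dispersion"]
# 0.234             # professionals most dispersed (resident 0.165 < family 0.196)
```

The dispersion ordering (residents most homogeneous, care professionals
most diverse in expressed sentiment) and the positive tilt of the
professional group are planted by the generator and recovered by the
pipeline; with the survey-derived lexicon the professionals' mean ternary
point is 38.6% positive / 34.2% negative / 27.2% neutral in this run.

The same stages are available from a shell:

```bash
caremine simulate --out-dir demo --seed 7
caremine freq unigrams demo/transcripts.jsonl -n 50
caremine correlate demo/transcripts.jsonl --groups resident,professional
caremine run-all --transcripts demo/transcripts.jsonl \
    --annotations demo/annotations.tsv --out-dir out --seed 7
```

`run-all` writes every table (frequencies, divergent words, lexicon,
ternary points, dispersion, topic clusters) with a metadata header and a
run manifest; outputs are byte-reproducible for a fixed seed.

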
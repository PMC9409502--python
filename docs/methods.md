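# Methods

## Scope and data model

`caremine` analyzes triadic nursing-home interviews: each interview has a
speaker group (`resident`, `family`, `professional`) and alternating
interviewer/interviewee turns. The utterance is the unit of analysis
throughout — it is the "sentence" that annotators judge in the sentiment
survey, the unit scored for the ternary interview summary, and the
boundary that bigrams and embedding windows never cross. Carrying one
unit through the whole pipeline keeps the survey-derived lexicon and the
interview scorer consistent.

## Preprocessing

Five steps, in order: (1) interviewer turns are dropped; (2) text is
NFC-normalized, lower-cased and split on non-letter characters
(hyphenated compounds split, digits and punctuation vanish, diacritics
survive); (3) stop words are removed by matching raw lower-cased tokens
against a packaged list of the 100 most common Dutch function words
(the standard frequency-ranked Dutch list truncated to 100 — a
documented stand-in, since any particular project's list is a local
choice); (4) tokens shorter than 3 characters are dropped (two-letter
Dutch words are nearly always function words); (5) stemming.

The stemmer is deliberately conservative: ordered suffix rules for
plurals (`-en`, `-s`, `-'s`) and diminutives (`-je`, `-tje`, `-pje`,
`-etje`, `-kje` and their plurals), with a 3-character minimum stem,
consonant undoubling (*mannen → man*) and final v/z devoicing
(*duiven → duif*, *huizen → huis*). `-igen` maps to `-ige` so adjectival
person nouns keep their final e (*verpleegkundigen → verpleegkundige*).
Final `-s` is stripped only after a consonant, so *huis* survives. Rules
are re-applied to a fixed point, which makes idempotence structural
rather than incidental; the cost is occasional over-stemming of
repeatedly strippable forms (*tekenen → tek*), accepted in exchange for
the fixed-point guarantee. A full Dutch stemmer over-stems far beyond
plurals/diminutives and would merge semantically distinct words, so it
is not the default; `DutchPreprocessor(stemmer=...)` is the adapter hook
for swapping one in.

Bigrams are counted on a parallel token stream that keeps stop words (but
applies the length filter and stemming), controlled by
`bigram_keep_stopwords`. High-frequency bigrams of interview speech
(*heel erg*, *wel goed*) are made of exactly the short evaluative words a
stop list can border on, so removing stop words first would erase the
most informative bigrams; the unigram tables always exclude them.
A side effect of removing stop words from the unigram stream is that
negation particles (*niet*) cannot appear in lexicon bigrams; negation
handling beyond surviving bigrams is out of scope.

## Frequencies and the Zipf diagnostic

Frequency tables are exact multiset counts per scope. The Zipf
diagnostic fits log₁₀(count) on log₁₀(rank) by OLS, ranks 1-based by
descending count with lexicographic tie-break, restricted to ranks with
count ≥ 2 so the hapax plateau does not dominate the fit; it returns the
slope and the Pearson r of the fit. Relative frequency is count divided
by the scope's token total.

## Cross-group correlation

Two groups' tables are aligned on the union vocabulary with add-k
smoothing (default k = 1) before converting to relative frequencies:
words used by only one group are informative off-diagonal points and
log(0) must never arise. Base-10 logs match standard plot axes. Pearson
r on fewer than 3 terms or with zero variance raises instead of silently
returning NaN. Divergent words are ranked by |log₁₀ fA − log₁₀ fB|.
Smoothing constant and intersection-only mode are configurable; exact
scale invariance of r under count rescaling holds in the unsmoothed
intersection mode (smoothing breaks it by a vanishing amount).

## Sentiment

The lexicon assigns each term
`score = (n_pos − n_neg) / (n_pos + n_neg + n_neu)`, counting one
context per (sentence, annotator) judgement; conflicting annotators all
count, with no adjudication step. Neutral contexts enter the denominator
with weight 0, diluting the score toward 0 — the natural extension of
the worked 9-positive/1-negative = 0.8 case to sentences judged neutral.
A term occurring twice in a sentence contributes two contexts
(configurable to once-per-sentence). Terms with fewer than
`min_occurrences = 3` contexts are dropped to suppress hapax noise.
Bigram lexicon entries come from within-sentence pairs of the same
preprocessed stream.

Sentence scoring takes the mean lexicon score over matched terms —
greedy left-to-right matching in which a matched bigram suppresses both
component unigrams — and classifies with a symmetric neutral band of
half-width τ = 0.1 (mean aggregation and τ are configurable; sum
aggregation is available). Sentences with no match are neutral with raw
score 0. Interview ternary points are the per-interview class
proportions ×100, with neutral computed as the complement so the three
percentages sum to exactly 100. Group dispersion is the mean pairwise
Euclidean distance between a group's points in 2-D barycentric
coordinates of the percentage simplex (unit-side triangle); groups are
ranked by it.

## Topic clustering

Keywords are stemmed noun/proper-noun tokens of interviewee utterances.
POS tagging is pluggable: a dictionary-backed `LexiconPOSTagger` (used
with the generator's ground-truth tags), a heuristic Dutch
derivational-suffix tagger, and an adapter for a full statistical tagger
that raises with an install hint when unavailable.

Embeddings are distributional: co-occurrence counts within a symmetric
5-token window inside utterances, converted to positive pointwise mutual
information and reduced to d = 50 dimensions by dense SVD, rows
L2-normalized (Euclidean k-means then approximates cosine geometry), with
a deterministic sign convention. A count-based PPMI–SVD factorization
was chosen over a sampled softmax predictor (word2vec-style) because it
targets the same co-occurrence statistics while being exactly
reproducible with no training schedule; keywords below `min_count = 3`
occurrences are excluded and logged.

k-means uses k-means++ seeding, best of 10 restarts, fixed seed. The
elbow rule is made explicit: over the candidate range, compute the
within-cluster sum of squares W(k), min-max normalize both axes, and
pick the interior k farthest (perpendicular distance) from the chord
joining the curve's endpoints; ties and perfectly linear curves resolve
to the smallest interior k. The 2-D view is a PCA projection (axes have
no meaning; the pairwise-distance rank correlation with the full space
is logged). The cluster report gives both readings of cluster size —
total keyword-token occurrences and the number of distinct utterances
containing a cluster keyword — because the two are routinely conflated;
cluster naming is left to the analyst.

## Synthetic corpus generator

The generator reproduces the statistical shape of the study conditions,
not Dutch grammar. Defaults: 39/37/49 interviews per group; interviewee
words per interview drawn negative-binomially around means 284.9 /
362.1 / 548.7 (dispersion size 20, giving a realistic ≈23% CV across
interviews); utterances of 1 + Poisson(11) tokens; an interviewer turn
before each interviewee turn sized so interviewers utter 30% of tokens.
The 2000-stem vocabulary is sampled Zipf(s = 1), with the 100 packaged
stop words occupying the top ranks.

Planted structure:

* **Topics** — each interviewee utterance draws one topic from the
  mixing weights; 25% of its tokens come uniformly from that topic's
  keyword list. Keywords have zero background probability, so their
  distributional signature is purely topical. The default mix has 12
  themes (relations, time, life experiences, care environment, … down to
  miscellaneous) with weights proportional to their prominence in
  long-term-care narratives.
* **Sentiment** — 60 planted terms with true scores evenly spread over
  [−1, 1]; 12% of tokens are sentiment terms. Each interview has a
  latent bias b ~ N(group mean, group spread) (resident 0.0 ± 0.15,
  family −0.15 ± 0.35, professional +0.15 ± 0.70 — homogeneous
  residents, slightly negative family members, positive and most diverse
  professionals) that tilts term choice by exp(2·b·score). The
  ground-truth ternary point of an interview applies the same
  mean-of-matched-scores ± 0.1 rule as the scorer to the realized
  utterances, so recovery checks are exact, not asymptotic.
* **Group tilt** — optionally each group over-uses a private set of
  background words (weight × (1 + tilt)), creating off-diagonal
  correlation words; tilt 0 means shared vocabulary.
* **Morphology** — content tokens surface inflected (plural/diminutive)
  at rate 0.25, using only suffixes verified at generation time to
  invert under the packaged stemmer, so preprocessing recovers planted
  stems exactly.

The survey samples interviewee utterances without replacement (default
coverage 56% of sentences, an annotator pool of 234 with plausible
demographics, 3 annotators per sentence — annotation redundancy is not
an externally fixed quantity, so it is a parameter) and labels each by
the planted rule, flipping to one of the other two labels with
probability `label_noise` (default 0.1, modest annotator disagreement).

What the generator does **not** emulate: grammar and word order beyond
topic/sentiment mixing, annotator-specific bias (noise is symmetric),
topic correlation with speaker group, and discourse structure. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
implemented correctly and are identifiable under the planted model — not
that the pipeline's substantive conclusions transfer to any particular
real corpus.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng`; a global seed
  fans out to stage seeds via a SHA-256 hash of the stage name (always
  < 2³¹). Corpus generation, survey sampling, embeddings, k-means and
  projections are bit-reproducible for a fixed seed.
* Ternary neutral percentages are computed as `100 − (pos + neg)` so the
  three parts sum to exactly 100 in floating point.
* Ties in every ranking break lexicographically; the elbow and argmax
  rules break toward the smallest k.
* Degenerate inputs raise informative errors rather than returning NaN:
  correlation with < 3 terms or zero variance, Zipf fits with < 3
  usable ranks, empty interviews in the ternary scorer, empty annotation
  sets, τ ≤ 0.
* A uniform-count table gets Zipf slope 0 with r reported as 0 (the
  correlation of a constant is undefined; 0 is the documented sentinel).

## Validation scale

The test suite validates at reduced scale chosen for tight feedback
loops: oracle recounts on a 12-interview corpus, lexicon recovery on a
180-interview / 200-term survey (~24k judgements), topic recovery on
45-interview corpora with 5 planted topics over 10 seeds, Zipf slope on
a structure-free ~120k-token corpus, and preprocessing contracts on 200
randomly configured miniature corpora. The Zipf ±0.15 recovery band is
asserted for the background sampler (topic and sentiment injection
deliberately distort the head of the rank-frequency curve; with default
shares the measured slope steepens to ≈ −1.29).

## Known limitations

* Absolute frequency counts and correlation coefficients of any real
  study are not reproducible without its transcripts, stop list and
  tokenizer; the pipeline's checks are therefore property-based
  (recovery of planted structure) rather than value-based.
* The heuristic noun tagger is crude; serious use on real Dutch text
  should plug in a statistical tagger via the adapter.
* The lexicon treats annotators as exchangeable; latent-truth annotator
  models are out of scope.
* At study scale (~10–27k preprocessed tokens per group) cross-group r
  lands near 0.72–0.78 from sampling noise alone even with identical
  vocabularies; the r ≥ 0.8 regime appears once groups reach roughly
  double that volume.
* With the default 12 overlapping topics and noisy background nouns, the
  elbow typically merges small themes (k ≈ 8); clean recovery of k
  requires well-separated topics, as the recovery tests plant.
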
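# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `fuzzysent`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline overview

Posts flow through six stages: acquisition (file or synthetic generator) →
preprocessing (keyword filter, dedup, validity, tokenization) → CBOW word
embedding → fuzzy-c-means sentiment centroids from the emotion lexicon →
nearest-centroid sentiment assignment → daily aggregation and before/after
Mann-Whitney comparisons.  One global seed deterministically derives the
sub-seed of every stochastic stage, so a (configuration, seed) pair fixes
every artifact byte for byte.

## Preprocessing

* **Keyword filter** is plain case-insensitive substring containment,
  emulating selection at the data-vendor query level rather than token-level
  matching.  Keywords are configuration; nothing is hard-coded.
* **Deduplication** keys on (kind, NFKC-normalized, whitespace-collapsed
  text) and keeps the earliest timestamp.  The post kind is part of the key
  deliberately: a tweet and a verbatim retweet of it are observations in two
  separate populations that the analysis compares, so both must survive.
* **Validity** removes records that contain no word character after
  stripping URLs (scheme-matched), `#`-prefixed hashtag tokens and
  `@`-mentions, attributing each removal to one reason (`url_only`,
  `hashtag_only`, `mention_only`, `symbol_only`, `empty`).  "No analyzable
  content" is necessarily an operationalization; the word-character heuristic
  is ours and is documented at the function.
* **Tokenization** is an interface.  The bundled `RegexTokenizer` (split on
  non-word characters) is deterministic and script-agnostic; an adapter slot
  for a MeCab-style morphological analyzer exists for real Japanese text and
  is optional at install time.  Posts yielding zero tokens are dropped with
  reason `untokenizable`.
* **Conservation** holds at every stage: input count = output count + the
  sum of attributed removals.  Day binning uses a configurable fixed offset
  (default UTC+9); naive timestamps are taken as study-local.

## CBOW embedding

The trainer implements the continuous bag-of-words objective with negative
sampling: the mean of the context words' input vectors predicts the center
word against `negative` noise words drawn from the unigram distribution to
the 3/4 power.  Defaults: dim 100, window 5, epochs 5, negative 5,
min_count 1, initial learning rate 0.025 decayed linearly to 1e-4.  Training
is mini-batched numpy, single-threaded and deterministic under the seed.

Two numerical conventions matter:

* **Row-update cap.**  Within a mini-batch the gradient contributions of a
  word repeated across rows are summed at a single parameter point.  On a
  small vocabulary this compounds into an effective learning rate far above
  alpha and diverges (sequential SGD would re-evaluate the sigmoid between
  repeats and self-saturate).  The accumulated update of a row is therefore
  scaled by `min(1, 16 / repeats)`.  On realistic vocabularies repeats are
  near 1 and the cap is inactive.
* **Lexicon coverage.**  Emotion-lexicon words absent from the corpus are
  appended as pseudo-documents so that every dictionary word has a vector in
  the same space (they retain their initialization if they truly never occur
  in context).  Tweets and lexicon are thus embedded jointly.

Document vectors are the unweighted mean of the distinct in-vocabulary word
vectors (`type_mean`); an occurrence-weighted mean (`token_mean`) is a
configuration switch.  A document with no in-vocabulary token is
*unjudgeable* — a distinguished outcome that propagates to the judged-count
bookkeeping, not an error.

## Fuzzy-c-means

The implementation is the standard Bezdek alternation (see README for the
objective and both updates), initialized from a seeded symmetric
Dirichlet(1) draw (rows uniform on the simplex) and terminated when the
elementwise maximum membership change falls below ε (default 1e-5, max 300
iterations).  Defaults: m = 2.0 (the conventional fuzzifier; the model is
defined for m > 1), c = 7 for the sentiment model.

Numerical conventions:

* **Coincident points.**  The membership formula is undefined when a datum
  sits exactly on a centroid; membership 1 is assigned there (split equally
  among several coincident centroids), the continuity limit.
* **Fuzzifier near 1.**  `d²^(−1/(m−1))` overflows for m barely above 1, so
  memberships are computed from distance ratios to the row minimum; ratios
  ≥ 1 raised to large negative exponents underflow harmlessly to zero.  The
  exact k-means limit is additionally available as a flag that replaces the
  membership update with a hard nearest-centroid assignment.
* The objective trace is recorded every iteration and is non-increasing (the
  alternating-minimization guarantee); tests assert it to 1e-8 relative.

**Cluster→sentiment matching.**  FCM clusters are anonymous, so the model
matches each cluster to the emotion whose lexicon words hold the most total
membership in it, solved exactly as a linear assignment problem.  Sentiment
centroids are then the matched FCM centroids (default), or, as a
configuration switch, the plain mean of each lexicon's words after pruning
to those with matched-cluster membership ≥ τ (default 0.5) — a
dictionary-reduction reading of the same construction; an emptied lexicon
falls back to all its words.  One FCM run over all lexicon words jointly
(c = 7) is used, rather than one run per emotion.

**Behavior in higher-dimensional embedding spaces.**  FCM with m = 2 and
random simplex initialization has a well-known degenerate attractor in which
all centroids collapse to the data's center of gravity and memberships to
1/c.  On this package's 140 lexicon-word vectors the benchmarks observe the
collapse from embedding dimension ≈ 8 upward even when the between/within
cluster separation is ~36×, while dimension 6 recovers the seven lexicon
clusters essentially perfectly.  The validation benchmarks therefore use a
compact embedding (dim 6, window 5, epochs 3); the general-purpose embedding
default stays at the conventional dim 100 for users embedding real text, who
should prefer the `pruned_word_mean` centroid mode or a lower m if they
observe near-uniform memberships.  This is a genuine limitation of the
method, not of the implementation.

**Assignment.**  A post receives the sentiment of the centroid at the
shortest Euclidean distance; all seven distances are reported.  Exact ties
resolve to the earlier label in the canonical order (anger, anxiety,
disgust, sadness, surprise, trust, joy).

## Statistics

* The statistical unit is one day: the proportion of judged posts of a
  (day, group) assigned each sentiment.  Days with no judged post are
  omitted.  "Daily sentiment value" is operationalized as this proportion.
* The window splits at the boundary's calendar date: before = strictly
  earlier days, after = boundary date onward.
* **Mann-Whitney U**, two-sided.  Mode `auto` uses exact enumeration of the
  rank-sum distribution when both n ≤ 8 and the pooled sample is tie-free,
  otherwise the normal approximation with tie correction and continuity
  correction.  The standardized deviate Z is reported in both modes and
  feeds the effect size r = |Z|/√N (the standard Mann-Whitney effect size;
  reported alongside every comparison).  Two identical constant samples are
  degenerate: p = 1 with a flag.  The continuity-corrected approximation
  agrees with the exact p to within 0.03 for tie-free samples with
  5 ≤ n1, n2 ≤ 8 (asserted exhaustively in tests); below n = 5 the
  approximation is coarser and `auto` never uses it there.
* **Families.**  14 before/after tests (7 sentiments × 2 groups) and 4
  polarity tests (positive/negative × before/after, tweet vs retweet,
  pooling sentiment-day observations: 2 × days positive, 4 × days negative
  per group).  Positive = {trust, joy}; negative = {anger, anxiety, disgust,
  sadness}; surprise belongs to neither pool.  No multiple-testing
  correction is applied by default (each table is read as a family of
  descriptive tests); Holm adjustment is available as an option and adds a
  `p_adjusted` column.
* Days are treated as independent observations.  No autocorrelation or
  changepoint modeling is attempted; with 15 observations per period this is
  a deliberate scope boundary, and serially correlated real data would make
  the nominal levels optimistic.

## Synthetic corpus generator

The generator emulates the study design the analysis assumes: a 30-day
window split 15/15 at the boundary; two post kinds with independent daily
volumes (defaults 140 tweets / 360 retweets per day, a ~28/72 split); seven
disjoint lexicons of 20 synthetic words each plus a 500-word filler
vocabulary; per-group sentiment mixtures that may change at the boundary;
posts of 8–16 tokens of which a `signal_strength` fraction (default 0.9)
comes from the planted sentiment's lexicon; timestamps uniform within the
day; and optional injected dirty records (URL-only, hashtag-only,
symbol-only, exact duplicates) plus an optional mode in which retweets copy
an earlier tweet's text with an "RT " prefix.  Words are random letter
strings — the pipeline is script-agnostic and tests must not depend on an
external morphological analyzer.  Injected duplicates are timestamped after
their source so deduplication keeps the labeled original.

What the generator does **not** emulate: natural-language morphology and
polysemy (real lexicon words are shared across emotions; synthetic lexicons
are disjoint), bursty daily volumes, follower networks, cascades and bots,
and multi-sentiment posts.  Passing the end-to-end benchmarks therefore
shows that the pipeline recovers planted structure under clean separation
assumptions — it does not certify accuracy on real text, where lexicon
overlap and embedding noise will lower both the judged fraction and
recovery.

`simulate_daily_table` additionally draws day-level sentiment counts
directly from the mixtures (one multinomial per day × group), the
perfect-recovery limit of the pipeline; it is the appropriate input for
power and type-I calibration studies of the day-level statistics, where
re-running text generation and embedding per replicate would add cost but no
information.

## Validation problem sizes

The benchmarks behind the acceptance suite use: 50 random FCM instances
(n ≤ 200, d ≤ 10, c ≤ 7); 20 replicates of 3 spherical Gaussian clusters
(n = 300, σ = 0.2, means 10σ apart — σ chosen so that the sampling error of
a 100-point cluster mean, ≈ σ√(2/100) ≈ 0.03, sits well inside the 0.1
recovery tolerance); exhaustive Mann-Whitney enumeration for all
n1, n2 ≤ 6; 10,000 null replicates at n = 15 vs 15 (the analytic size of the
continuity-corrected test there is 0.0453); one full end-to-end study at
500 posts/day/group over 30 days (≈ 30,000 posts); and 100 day-table
replicates each for shift-detection power (+0.15 joy in the retweet group
after the boundary) and null calibration of the 14-test family.

## Known limitations

* Tweet-vector construction (mean pooling) and the cluster→sentiment
  matching rule are reasonable defaults, not canonical; both are
  configuration points.
* FCM's high-dimension degeneracy (above) constrains the embedding
  dimension under the default fuzzifier.
* The Mann-Whitney normal approximation is used for the 15-vs-15 design;
  its exact size there is slightly conservative (0.0453 at nominal 0.05).
* The generator's disjoint lexicons make the assignment task easier than
  real emotion dictionaries, which share words across categories.
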
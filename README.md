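# fuzzysent

Fuzzy-c-means sentiment analysis of short social-media posts, with
before/after intervention statistics.

## The problem

Public-health surveillance increasingly reads population mood off social
media (infodemiology): how did sentiment shift when an intervention — say, a
state-of-emergency declaration — took effect, and do original posts (tweets)
and reshared posts (retweets) behave differently?  Answering this from a raw
post stream requires a full pipeline: cleaning a keyword-sampled corpus,
embedding its vocabulary, giving a seven-category emotion lexicon (anger,
anxiety, disgust, sadness, surprise, trust, joy) geometric form, labeling
every post, and testing daily sentiment proportions across the boundary.

`fuzzysent` implements that pipeline as a library with a thin CLI.  Because
real platform feeds are proprietary, it ships a first-class synthetic corpus
generator that plants known sentiment mixtures, so every stage is testable
and the whole method can be validated by simulation.

## The model

**Embedding.** Continuous bag-of-words (CBOW) word vectors with negative
sampling are trained on the tokenized corpus (lexicon words are guaranteed a
vector in the same space).  A post's document vector is the mean of its
in-vocabulary word vectors; a post with no known word is *unjudgeable*.

**Sentiment centroids.** The embedded lexicon words are soft-clustered with
Bezdek fuzzy-c-means (c = 7), which minimizes

$$J(U,V) = \sum_{i=1}^{n}\sum_{t=1}^{c} u_{it}^{m}\,\lVert x_i - v_t\rVert^2,
\qquad \sum_t u_{it} = 1,$$

by alternating the centroid update
$v_t = \sum_i u_{it}^m x_i \big/ \sum_i u_{it}^m$
with the membership update
$u_{it} = \left[\sum_s (\lVert x_i - v_t\rVert / \lVert x_i - v_s\rVert)^{2/(m-1)}\right]^{-1}$
until $\max_{i,t} |u_{it}^{(p+1)} - u_{it}^{(p)}| < \varepsilon$.  The
fuzzifier $m > 1$ controls softness; $m \to 1$ recovers k-means.  Each
cluster is matched to the emotion whose words it best absorbs (an assignment
problem on membership mass), and every post is labeled by the nearest
sentiment centroid (Euclidean distance; ties break in canonical label order).

**Statistics.** Sentiment calls are aggregated into daily proportions per
(day, group); the window splits at the boundary into before/after periods.
Two-sided Mann-Whitney U tests compare (i) before vs after for each of the
14 (sentiment, group) pairs, and (ii) tweet vs retweet within each (polarity,
period), pooling positive = {trust, joy} and negative = {anger, anxiety,
disgust, sadness} over sentiment-day observations.  Effect sizes are
$r = |Z|/\sqrt{N}$ with a tie-corrected, continuity-corrected $Z$.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/04_sentiment_model.py` trains the full sentiment model on a
3,000-post synthetic corpus and prints:

```
vocabulary: 640 words, dim=6
FCM converged after 22 iterations; mean max-membership 0.750
cluster -> sentiment map: {0: 'surprise', 1: 'trust', 2: 'anxiety', 3: 'sadness', 4: 'anger', 5: 'disgust', 6: 'joy'}
judged 3000/3000 posts (0 unjudgeable)
planted-label recovery: 99.9%
sample call: p00000000 -> sadness; nearest distances [('sadness', 0.129...), ('joy', 0.302...)]
```

Every post was judgeable, the seven fuzzy clusters mapped one-to-one onto the
seven lexicons, and 99.9% of posts received their planted sentiment.
`examples/05_before_after_analysis.py` runs the complete pipeline with a
planted +0.15 joy shift in the retweet group after the boundary and prints
the comparison tables; the joy/retweet test comes out at
p ≈ 3e-06 with effect size r ≈ 0.85, while the pooled negative
tweet-vs-retweet contrast is significant only in the "after" period — the
shape of result the pipeline is designed to surface.

The same pipeline is scriptable from a shell:

```sh
fuzzysent run --config examples/run.yaml --out results/
```

or stage by stage (`generate`, `preprocess`, `embed`, `build-model`,
`assign`, `compare`), resuming from the artifacts in the output directory.

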
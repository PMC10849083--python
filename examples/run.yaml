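# Sample run configuration for the fuzzysent CLI.
#
#   fuzzysent run --config examples/run.yaml --out results/
#
# Exactly one input source is active: the synthetic block below, or a pair of
# posts_path (JSON Lines: {"id","kind","created_at","text"}) and
# dictionary_path (CSV: sentiment,word) together with a boundary date.

seed: 0

synthetic:
  n_days: 30
  boundary_day: 15          # first "after" day; 15/15 split
  posts_per_day_tweet: 140
  posts_per_day_retweet: 360
  lexicon_size_per_sentiment: 20
  filler_vocab_size: 500
  signal_strength: 0.9
  tokens_per_post: [8, 16]
  dirty_fraction: 0.02
  start_date: 2020-03-23

# posts_path: data/posts.jsonl
# dictionary_path: data/dictionary.csv
# boundary: 2020-04-07
# keywords: ["コロナ", "COVID-19", "新型肺炎"]

tz_offset_hours: 9.0

embedding:
  dim: 6        # compact dimension suited to the 7-lexicon synthetic corpus
  window: 5
  epochs: 3
  negative: 5
  min_count: 1

fcm:
  c: 7
  m: 2.0
  epsilon: 1.0e-5
  max_iter: 300

centroid_mode: fcm        # or pruned_word_mean
doc_weighting: type_mean  # or token_mean
mw_mode: auto             # exact | normal_approx | auto
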
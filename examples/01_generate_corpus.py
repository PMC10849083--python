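"""Generate a labeled synthetic corpus of tweets and retweets.

Builds a 10-day corpus with a planted sentiment mixture per group, injects
dirty records, and prints what the generator produced.  The printed counts
show the configured per-day volumes and the dirty-record bookkeeping that the
preprocessing stage is expected to undo.
"""

from fuzzysent import SyntheticConfig, generate_corpus, generate_dictionary, inject_dirty_records

config = SyntheticConfig(
    n_days=10,
    boundary_day=5,
    posts_per_day_tweet=30,
    posts_per_day_retweet=70,
    dirty_fraction=0.05,
    rng_seed=42,
)
dictionary = generate_dictionary(config)
corpus = inject_dirty_records(generate_corpus(config, dictionary), config)

print(f"posts generated: {len(corpus.posts)}")
print(f"  clean (labeled): {len(corpus.true_sentiment)}")
print(f"  dirty (injected): {len(corpus.dirty_reasons)}")
first = corpus.posts[0]
print(f"sample post: id={first.id} kind={first.kind} day={first.created_at.date()}")
print(f"  text: {first.text[:60]}...")
print(f"  true sentiment: {corpus.true_sentiment[first.id]}")
print(f"lexicon: 7 sentiments x {len(dictionary.words['joy'])} words, e.g. "
      f"joy -> {dictionary.words['joy'][:3]}")
# Each clean post's tokens are drawn mostly (signal_strength) from its true
# sentiment's lexicon; the dirty records are URL-only, hashtag-only,
# symbol-only or duplicate texts that carry no label.
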
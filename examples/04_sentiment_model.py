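"""Embed a corpus, build fuzzy sentiment centroids, and label posts.

Trains CBOW vectors on a small synthetic corpus, fuzzy-clusters the embedded
emotion lexicon into 7 labeled centroids, assigns each post the sentiment
with the shortest vector distance, and scores the calls against the planted
truth.
"""

import numpy as np

from fuzzysent import (
    EmbeddingConfig,
    FCMConfig,
    SyntheticConfig,
    assign_many,
    build_sentiment_centroids,
    generate_corpus,
    generate_dictionary,
    train_cbow,
    vectorize_posts,
)
from fuzzysent.preprocess import preprocess_posts

config = SyntheticConfig(
    n_days=10, boundary_day=5, posts_per_day_tweet=150, posts_per_day_retweet=150,
    rng_seed=7,
)
dictionary = generate_dictionary(config)
corpus = generate_corpus(config, dictionary)
clean, _ = preprocess_posts(corpus.posts)

embedding = train_cbow(
    clean, EmbeddingConfig(dim=6, epochs=3, seed=1),
    extra_vocabulary=dictionary.all_words(),
)
print(f"vocabulary: {len(embedding)} words, dim={embedding.dim}")

centroids, partition = build_sentiment_centroids(
    dictionary, embedding, FCMConfig(c=7, m=2.0, seed=2)
)
print(f"FCM converged after {partition.n_iter} iterations; "
      f"mean max-membership {partition.U.max(axis=1).mean():.3f}")
print(f"cluster -> sentiment map: {dict(sorted(centroids.cluster_map.items()))}")

docs, unjudgeable = vectorize_posts(clean, embedding)
calls = assign_many(docs, centroids)
accuracy = np.mean([corpus.true_sentiment[c.post_id] == c.sentiment for c in calls])
print(f"judged {len(calls)}/{len(clean)} posts ({len(unjudgeable)} unjudgeable)")
print(f"planted-label recovery: {accuracy:.1%}")
call = calls[0]
print(f"sample call: {call.post_id} -> {call.sentiment}; nearest distances "
      f"{sorted(call.distances.items(), key=lambda kv: kv[1])[:2]}")
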
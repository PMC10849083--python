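"""Synthetic corpus generator: determinism, mixtures, dirty-record injection."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from fuzzysent import (
    SyntheticConfig,
    generate_corpus,
    generate_dictionary,
    inject_dirty_records,
    uniform_mixture,
)
from fuzzysent.types import SENTIMENTS


def corpus_fingerprint(corpus) -> str:
    return json.dumps(
        [
            (p.id, p.kind, p.created_at.isoformat(), p.text)
            for p in corpus.posts
        ]
    )


class TestGenerateDictionary:
    def test_minimal_size_disjoint(self):
        cfg = SyntheticConfig(lexicon_size_per_sentiment=1, rng_seed=42)
        d = generate_dictionary(cfg)
        assert all(len(d.words[s]) == 1 for s in SENTIMENTS)
        assert len({w for s in SENTIMENTS for w in d.words[s]}) == 7

    def test_deterministic(self):
        cfg = SyntheticConfig(rng_seed=42)
        assert generate_dictionary(cfg).words == generate_dictionary(cfg).words

    def test_twenty_words_per_sentiment_no_overlap(self):
        cfg = SyntheticConfig(lexicon_size_per_sentiment=20, rng_seed=7)
        d = generate_dictionary(cfg)
        all_words = d.all_words()
        assert len(all_words) == 140
        assert len(set(all_words)) == 140

    def test_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(lexicon_size_per_sentiment=0)


class TestGenerateCorpus:
    def test_post_counts(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=10, posts_per_day_retweet=10
        )
        corpus = generate_corpus(cfg)
        assert len(corpus.posts) == 40
        assert sum(p.kind == "tweet" for p in corpus.posts) == 20

    def test_point_mass_mixture(self):
        joy_only = {s: (1.0 if s == "joy" else 0.0) for s in SENTIMENTS}
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=15, posts_per_day_retweet=15,
            mixture_before=joy_only, mixture_after=joy_only,
        )
        corpus = generate_corpus(cfg)
        assert set(corpus.true_sentiment.values()) == {"joy"}

    def test_uniform_mixture_frequencies(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=2, posts_per_day_tweet=2500,
            posts_per_day_retweet=2500, tokens_per_post=(2, 4), rng_seed=5,
        )
        corpus = generate_corpus(cfg)
        n = len(corpus.posts)
        assert n == 10_000
        p = 1 / 7
        se = np.sqrt(p * (1 - p) / n)
        for s in SENTIMENTS:
            freq = sum(v == s for v in corpus.true_sentiment.values()) / n
            assert abs(freq - p) < 3 * se

    def test_timestamps_and_kind_match_schedule(self, small_config, small_corpus):
        start = small_config.start_date
        by_day = {}
        for p in small_corpus.posts:
            day_idx = (p.created_at.date() - start).days
            assert 0 <= day_idx < small_config.n_days
            by_day.setdefault((day_idx, p.kind), 0)
            by_day[(day_idx, p.kind)] += 1
        for day_idx in range(small_config.n_days):
            assert by_day[(day_idx, "tweet")] == small_config.posts_per_day_tweet
            assert by_day[(day_idx, "retweet")] == small_config.posts_per_day_retweet

    def test_every_clean_post_labeled(self, small_corpus):
        assert {p.id for p in small_corpus.posts} == set(small_corpus.true_sentiment)

    def test_determinism_byte_identical(self, small_config):
        a = generate_corpus(small_config)
        b = generate_corpus(small_config)
        assert corpus_fingerprint(a) == corpus_fingerprint(b)

    def test_empty_lexicon_rejected(self, small_config):
        from fuzzysent.types import SentimentDictionary

        words = {s: ("w" + s,) for s in SENTIMENTS}
        words["joy"] = ()
        with pytest.raises(ValueError, match="empty"):
            generate_corpus(small_config, SentimentDictionary(words=words))

    def test_planted_shift_changes_label_rates(self):
        shifted = uniform_mixture()
        shifted["joy"] += 0.3
        rest = (1 - shifted["joy"]) / 6
        shifted = {s: (shifted["joy"] if s == "joy" else rest) for s in SENTIMENTS}
        cfg = SyntheticConfig(
            n_days=4, boundary_day=2, posts_per_day_tweet=500, posts_per_day_retweet=0,
            tokens_per_post=(2, 4), mixture_after=shifted, rng_seed=3,
        )
        corpus = generate_corpus(cfg)
        before = [p.id for p in corpus.posts if (p.created_at.date() - cfg.start_date).days < 2]
        after = [p.id for p in corpus.posts if (p.created_at.date() - cfg.start_date).days >= 2]
        joy_before = np.mean([corpus.true_sentiment[i] == "joy" for i in before])
        joy_after = np.mean([corpus.true_sentiment[i] == "joy" for i in after])
        assert joy_after > joy_before + 0.15

    def test_separability_with_full_signal(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=30, posts_per_day_retweet=30,
            signal_strength=1.0, rng_seed=9,
        )
        corpus = generate_corpus(cfg)
        lexicons = {s: set(corpus.dictionary.words[s]) for s in SENTIMENTS}
        for p in corpus.posts:
            hits = [s for s in SENTIMENTS if set(p.text.split()) & lexicons[s]]
            assert hits == [corpus.true_sentiment[p.id]]

    def test_retweet_copy_mode(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=50, posts_per_day_retweet=50,
            retweet_copy_fraction=1.0, rng_seed=4,
        )
        corpus = generate_corpus(cfg)
        tweets = {p.text for p in corpus.posts if p.kind == "tweet"}
        rts = [p for p in corpus.posts if p.kind == "retweet"]
        assert all(p.text.startswith("RT ") and p.text[3:] in tweets for p in rts)

    def test_mixture_fidelity_chi2(self):
        """Chi-square GOF at alpha=.01 rejects at most once over 20 seeds."""
        expected = np.full(7, 10_000 / 7)
        failures = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_days=1, boundary_day=1, posts_per_day_tweet=5000,
                posts_per_day_retweet=5000, tokens_per_post=(2, 3), rng_seed=seed,
            )
            corpus = generate_corpus(cfg)
            counts = np.array(
                [sum(v == s for v in corpus.true_sentiment.values()) for s in SENTIMENTS]
            )
            if sps.chisquare(counts, expected).pvalue < 0.01:
                failures += 1
        assert failures <= 1


class TestInjectDirty:
    def test_zero_fraction_identity(self, small_config, small_corpus):
        assert inject_dirty_records(small_corpus, small_config) is small_corpus

    def test_counts_and_flags(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=25, posts_per_day_retweet=25,
            dirty_fraction=0.1, rng_seed=2,
        )
        corpus = generate_corpus(cfg)
        dirty = inject_dirty_records(corpus, cfg)
        assert len(dirty.posts) == 110
        assert len(dirty.dirty_reasons) == 10
        assert dirty.posts[:100] == corpus.posts  # originals untouched

    def test_duplicates_copy_original_text(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=1, posts_per_day_tweet=25, posts_per_day_retweet=25,
            dirty_fraction=0.2, rng_seed=2,
        )
        dirty = inject_dirty_records(generate_corpus(cfg), cfg)
        originals = {p.text for p in dirty.posts if p.id not in dirty.dirty_reasons}
        dup_ids = [i for i, r in dirty.dirty_reasons.items() if r == "duplicate"]
        assert dup_ids
        by_id = {p.id: p for p in dirty.posts}
        assert all(by_id[i].text in originals for i in dup_ids)
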
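"""Synthetic corpus and lexicon generator.

Generates labeled corpora with the statistical structure the downstream
analysis assumes: two post kinds (original "tweet" posts and reshared
"retweet" posts) with their own sentiment mixtures, per-day post volumes over
a calendar window, a planted change in the sentiment mixture at a boundary
day, sentiment-loaded vocabularies per emotion category, and optionally
injected invalid records (URL-only, hashtag-only, symbol-only, duplicates)
for exercising the preprocessing stage.

Words are synthetic letter strings, not natural language: the pipeline is
script-agnostic and the generator must not depend on any external
morphological analyzer.  Every draw is controlled by ``rng_seed``; identical
configurations produce byte-identical corpora.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Mapping

import numpy as np

from .types import POST_KINDS, SENTIMENTS, RawPost, SentimentDictionary

_MIXTURE_TOL = 1e-9

GroupMixtures = dict[str, dict[str, float]]


def _normalize_mixture(
    mixture: Mapping[str, float] | Mapping[str, Mapping[str, float]],
) -> GroupMixtures:
    """Accept either one sentiment->p map (broadcast to both groups) or a
    per-group {"tweet": {...}, "retweet": {...}} map; validate simplex."""
    if set(mixture) <= set(POST_KINDS):
        per_group = {k: dict(v) for k, v in mixture.items()}  # type: ignore[arg-type]
        for k in POST_KINDS:
            if k not in per_group:
                raise ValueError(f"mixture missing group {k!r}")
    else:
        flat = {k: float(v) for k, v in mixture.items()}  # type: ignore[arg-type]
        per_group = {k: dict(flat) for k in POST_KINDS}
    for group, mix in per_group.items():
        if set(mix) != set(SENTIMENTS):
            raise ValueError(
                f"mixture for {group!r} must assign a probability to each of "
                f"{SENTIMENTS}"
            )
        probs = np.array([mix[s] for s in SENTIMENTS], dtype=float)
        if (probs < 0).any():
            raise ValueError(f"mixture for {group!r} has negative probabilities")
        if abs(probs.sum() - 1.0) > _MIXTURE_TOL:
            raise ValueError(
                f"mixture for {group!r} sums to {probs.sum()!r}, expected 1"
            )
    return per_group


def uniform_mixture() -> dict[str, float]:
    """Uniform sentiment mixture (1/7 each)."""
    return {s: 1.0 / len(SENTIMENTS) for s in SENTIMENTS}


@dataclass
class SyntheticConfig:
    """Study-design parameters for corpus generation.

    Defaults emulate the study design the analysis targets: a 30-day window
    split 15/15 at the boundary (two weeks before and after an intervention),
    a roughly 28/72 tweet/retweet volume split, seven 20-word emotion
    lexicons, and posts whose token stream is dominated (``signal_strength``)
    by the planted emotion's lexicon.
    """

    n_days: int = 30
    boundary_day: int = 15
    posts_per_day_tweet: int = 140
    posts_per_day_retweet: int = 360
    lexicon_size_per_sentiment: int = 20
    filler_vocab_size: int = 500
    mixture_before: Mapping[str, float] | Mapping[str, Mapping[str, float]] = field(
        default_factory=uniform_mixture
    )
    mixture_after: Mapping[str, float] | Mapping[str, Mapping[str, float]] = field(
        default_factory=uniform_mixture
    )
    signal_strength: float = 0.9
    tokens_per_post: tuple[int, int] = (8, 16)
    dirty_fraction: float = 0.0
    rng_seed: int = 0
    start_date: date = date(2020, 3, 23)
    #: Fraction of retweets that verbatim-copy an earlier tweet's text with an
    #: "RT " prefix instead of being independently generated.
    retweet_copy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.lexicon_size_per_sentiment < 1:
            raise ValueError("lexicon_size_per_sentiment must be >= 1")
        if not (0 <= self.boundary_day <= self.n_days):
            raise ValueError("boundary_day must lie in [0, n_days]")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if not (0.0 <= self.dirty_fraction < 1.0):
            raise ValueError("dirty_fraction must lie in [0, 1)")
        lo, hi = self.tokens_per_post
        if lo < 1 or hi < lo:
            raise ValueError("tokens_per_post must be a range (lo, hi) with 1 <= lo <= hi")
        self.mixture_before = _normalize_mixture(self.mixture_before)
        self.mixture_after = _normalize_mixture(self.mixture_after)


@dataclass(frozen=True)
class LabeledCorpus:
    """A synthetic corpus with ground-truth sentiment labels.

    ``true_sentiment`` maps each clean post id to its planted label; injected
    dirty records are listed in ``dirty_reasons`` (id -> reason) and carry no
    label.
    """

    posts: tuple[RawPost, ...]
    true_sentiment: dict[str, str]
    dictionary: SentimentDictionary
    dirty_reasons: dict[str, str] = field(default_factory=dict)

    def clean_posts(self) -> tuple[RawPost, ...]:
        return tuple(p for p in self.posts if p.id not in self.dirty_reasons)


def _random_words(
    rng: np.random.Generator, n: int, used: set[str], length: int = 7
) -> list[str]:
    """Draw ``n`` distinct random lowercase letter strings not in ``used``."""
    letters = np.array(list(string.ascii_lowercase))
    out: list[str] = []
    while len(out) < n:
        word = "".join(rng.choice(letters, size=length))
        if word not in used:
            used.add(word)
            out.append(word)
    return out


def generate_dictionary(config: SyntheticConfig) -> SentimentDictionary:
    """Generate seven pairwise-disjoint synthetic emotion lexicons.

    Deterministic under ``config.rng_seed``; independent of every other
    configuration field except ``lexicon_size_per_sentiment``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0]))
    used: set[str] = set()
    words = {
        s: tuple(_random_words(rng, config.lexicon_size_per_sentiment, used))
        for s in SENTIMENTS
    }
    return SentimentDictionary(words=words)


def _filler_vocabulary(config: SyntheticConfig, dictionary: SentimentDictionary) -> list[str]:
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    used = set(dictionary.all_words())
    return _random_words(rng, config.filler_vocab_size, used)


def generate_corpus(
    config: SyntheticConfig, dictionary: SentimentDictionary | None = None
) -> LabeledCorpus:
    """Generate a labeled corpus of tweets and retweets.

    For each calendar day and group the configured number of posts is
    emitted.  Each post's sentiment is drawn from the period-appropriate
    mixture for its group; each of its tokens independently comes from that
    sentiment's lexicon with probability ``signal_strength`` and from the
    filler vocabulary otherwise.  Timestamps are uniform within the day and
    timezone-naive.
    """
    if dictionary is None:
        dictionary = generate_dictionary(config)
    for s in SENTIMENTS:
        if len(dictionary.words[s]) == 0:
            raise ValueError(f"lexicon for sentiment {s!r} is empty")
    filler = np.array(_filler_vocabulary(config, dictionary))
    lexicons = {s: np.array(dictionary.words[s]) for s in SENTIMENTS}
    sentiments_arr = np.array(SENTIMENTS)

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    posts: list[RawPost] = []
    labels: dict[str, str] = {}
    counter = 0
    lo, hi = config.tokens_per_post
    n_per_group = {
        "tweet": config.posts_per_day_tweet,
        "retweet": config.posts_per_day_retweet,
    }
    tweet_pool: list[tuple[str, str]] = []  # (text, label) of generated tweets

    for day_idx in range(config.n_days):
        day = config.start_date + timedelta(days=day_idx)
        mixtures = (
            config.mixture_before if day_idx < config.boundary_day else config.mixture_after
        )
        for group in POST_KINDS:
            probs = np.array([mixtures[group][s] for s in SENTIMENTS])
            for _ in range(n_per_group[group]):
                ts = datetime.combine(day, datetime.min.time()) + timedelta(
                    seconds=float(rng.uniform(0, 86400))
                )
                pid = f"p{counter:08d}"
                counter += 1
                if (
                    group == "retweet"
                    and tweet_pool
                    and rng.random() < config.retweet_copy_fraction
                ):
                    src_text, src_label = tweet_pool[rng.integers(len(tweet_pool))]
                    text, label = "RT " + src_text, src_label
                else:
                    label = str(rng.choice(sentiments_arr, p=probs))
                    k = int(rng.integers(lo, hi + 1))
                    from_lexicon = rng.random(k) < config.signal_strength
                    toks = np.where(
                        from_lexicon,
                        rng.choice(lexicons[label], size=k),
                        rng.choice(filler, size=k),
                    )
                    text = " ".join(toks)
                    if group == "tweet":
                        tweet_pool.append((text, label))
                posts.append(RawPost(id=pid, kind=group, created_at=ts, text=text))
                labels[pid] = label

    return LabeledCorpus(posts=tuple(posts), true_sentiment=labels, dictionary=dictionary)


def simulate_daily_table(
    config: SyntheticConfig, rng: np.random.Generator | None = None
):
    """Simulate the daily sentiment-proportion table directly from the mixtures.

    Bypasses text generation entirely: for each (day, group) the per-sentiment
    counts are one multinomial draw of the configured post volume from the
    period-appropriate mixture.  This is the idealized limit of the full
    pipeline with perfect sentiment recovery, and is the appropriate input
    for power and type-I calibration studies of the day-level statistics.

    Returns a DataFrame with columns day, group, sentiment, count, proportion.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_per_group = {
        "tweet": config.posts_per_day_tweet,
        "retweet": config.posts_per_day_retweet,
    }
    rows = []
    for day_idx in range(config.n_days):
        day = config.start_date + timedelta(days=day_idx)
        mixtures = (
            config.mixture_before if day_idx < config.boundary_day else config.mixture_after
        )
        for group in POST_KINDS:
            n = n_per_group[group]
            if n == 0:
                continue
            probs = np.array([mixtures[group][s] for s in SENTIMENTS])
            counts = rng.multinomial(n, probs)
            for s, cnt in zip(SENTIMENTS, counts):
                rows.append((day, group, s, int(cnt), cnt / n))
    return pd.DataFrame(rows, columns=["day", "group", "sentiment", "count", "proportion"])


_DIRTY_KINDS = ("url_only", "hashtag_only", "symbol_only", "duplicate")
_SYMBOLS = np.array(list("!?.,;:()[]{}<>~^*+-=|/\\"))


def inject_dirty_records(corpus: LabeledCorpus, config: SyntheticConfig) -> LabeledCorpus:
    """Append invalid records to a corpus for preprocessing tests.

    ``round(dirty_fraction * n_clean)`` records are appended, cycling through
    URL-only, hashtag-only, symbol-only, and exact-duplicate texts; each is
    flagged in ``dirty_reasons``.  Original posts are untouched.
    """
    n_dirty = int(round(config.dirty_fraction * len(corpus.posts)))
    if n_dirty == 0:
        return corpus
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    window_seconds = config.n_days * 86400.0
    new_posts = list(corpus.posts)
    reasons = dict(corpus.dirty_reasons)
    originals = corpus.posts
    for j in range(n_dirty):
        reason = _DIRTY_KINDS[j % len(_DIRTY_KINDS)]
        ts = datetime.combine(config.start_date, datetime.min.time()) + timedelta(
            seconds=float(rng.uniform(0, window_seconds))
        )
        pid = f"d{j:08d}"
        if reason == "url_only":
            slug = "".join(rng.choice(np.array(list(string.ascii_lowercase)), size=8))
            text, kind = f"https://t.co/{slug}", "tweet"
        elif reason == "hashtag_only":
            tag = "".join(rng.choice(np.array(list(string.ascii_lowercase)), size=6))
            text, kind = f"#{tag}", "tweet"
        elif reason == "symbol_only":
            text = "".join(rng.choice(_SYMBOLS, size=int(rng.integers(3, 10))))
            kind = "tweet"
        else:  # exact duplicate of an existing post, same kind
            src = originals[rng.integers(len(originals))]
            text, kind = src.text, src.kind
            # later than the source so dedup keeps the labeled original
            ts = src.created_at + timedelta(seconds=float(rng.uniform(1, 3600)))
        new_posts.append(RawPost(id=pid, kind=kind, created_at=ts, text=text))
        reasons[pid] = reason
    return LabeledCorpus(
        posts=tuple(new_posts),
        true_sentiment=dict(corpus.true_sentiment),
        dictionary=corpus.dictionary,
        dirty_reasons=reasons,
    )
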
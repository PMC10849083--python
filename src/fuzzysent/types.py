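"""Core record types shared across the pipeline.

A post flows through the pipeline as :class:`RawPost` (as ingested) and
:class:`CleanPost` (tokenized, day-binned).  Sentiment labels use a fixed
seven-category emotion scheme (anger, anxiety, disgust, sadness, surprise,
trust, joy); the tuple :data:`SENTIMENTS` is the canonical order used for
deterministic tie-breaking throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Mapping, Sequence

#: Canonical sentiment order. Ties (e.g. equidistant centroids) resolve to the
#: earlier label in this tuple.
SENTIMENTS: tuple[str, ...] = (
    "anger",
    "anxiety",
    "disgust",
    "sadness",
    "surprise",
    "trust",
    "joy",
)

#: Polarity map used for pooled positive/negative comparisons. "surprise" is
#: deliberately in neither pool.
POSITIVE_SENTIMENTS: tuple[str, ...] = ("trust", "joy")
NEGATIVE_SENTIMENTS: tuple[str, ...] = ("anger", "anxiety", "disgust", "sadness")

POST_KINDS: tuple[str, ...] = ("tweet", "retweet")


@dataclass(frozen=True)
class RawPost:
    """One social-media record as ingested.

    Parameters
    ----------
    id:
        Opaque unique identifier.
    kind:
        ``"tweet"`` (original post) or ``"retweet"`` (reshared post).
    created_at:
        Posting instant; timezone-naive timestamps are interpreted as local
        study time.
    text:
        Raw unicode text.
    """

    id: str
    kind: str
    created_at: datetime
    text: str

    def __post_init__(self) -> None:
        if self.kind not in POST_KINDS:
            raise ValueError(f"kind must be one of {POST_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class CleanPost:
    """A post that survived filtering, with its token sequence and calendar day."""

    id: str
    kind: str
    created_at: datetime
    text: str
    tokens: tuple[str, ...]
    day: date

    def __post_init__(self) -> None:
        if self.kind not in POST_KINDS:
            raise ValueError(f"kind must be one of {POST_KINDS}, got {self.kind!r}")
        if not self.tokens:
            raise ValueError("CleanPost requires a non-empty token sequence")


@dataclass(frozen=True)
class SentimentDictionary:
    """Seven labeled word lists (an emotion lexicon).

    ``words`` maps each sentiment label to an ordered tuple of words.  Labels
    must be exactly the seven canonical sentiments; word lists need not be
    disjoint in general (real lexicons share words), though the synthetic
    generator produces disjoint ones.
    """

    words: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.words) != set(SENTIMENTS):
            raise ValueError(
                f"dictionary must cover exactly the labels {SENTIMENTS}, "
                f"got {sorted(self.words)}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return SENTIMENTS

    def all_words(self) -> list[str]:
        """All dictionary words in canonical label order (may contain repeats)."""
        return [w for s in SENTIMENTS for w in self.words[s]]

    def label_of(self) -> dict[str, list[str]]:
        """Invert the lexicon: word -> list of labels containing it."""
        out: dict[str, list[str]] = {}
        for s in SENTIMENTS:
            for w in self.words[s]:
                out.setdefault(w, []).append(s)
        return out
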
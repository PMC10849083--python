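"""Filtering, deduplication and tokenization of raw posts.

The stages mirror how keyword-sampled social-media corpora are cleaned before
sentiment analysis: keyword retention, removal of duplicate posts, removal of
records with no analyzable text (URL-only, hashtag-only, symbol-only), and
tokenization through a pluggable tokenizer.  Every stage preserves input
order and reports the number of records it removed by reason, so that
``n_input = n_output + removed`` reconciles at each step.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Callable, Iterable, Protocol, Sequence

from .types import CleanPost, RawPost

#: Default keyword set for corpus selection (a COVID-19 topic query).
DEFAULT_KEYWORDS: frozenset[str] = frozenset({"コロナ", "COVID-19", "新型肺炎"})

#: Day binning defaults to UTC+9 (Japan Standard Time); timezone-naive
#: timestamps are assumed to already be in study-local time.
DEFAULT_TZ_OFFSET_HOURS: float = 9.0


class TokenizerInterface(Protocol):
    """A tokenizer is a pure, deterministic function text -> token sequence."""

    def __call__(self, text: str) -> Sequence[str]: ...


class RegexTokenizer:
    """Deterministic fallback tokenizer splitting on non-word characters.

    Suitable for space-delimited or synthetic text; it is NOT a morphological
    analyzer and will not segment unsegmented Japanese.
    """

    _word = re.compile(r"\w+", re.UNICODE)

    def __call__(self, text: str) -> list[str]:
        return self._word.findall(text)


class MeCabTokenizer:
    """Adapter slot for a MeCab-style morphological analyzer.

    Requires the optional ``fugashi`` dependency (with a system MeCab and,
    ideally, a neologism dictionary such as mecab-ipadic-NEologd).  The
    adapter surfaces MeCab's word segmentation through the tokenizer
    interface; it is optional at install time and never used by the test
    suite.
    """

    def __init__(self, tagger_args: str = "") -> None:
        try:
            import fugashi  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "MeCabTokenizer requires the optional 'fugashi' package "
                "(pip install fugashi[unidic-lite]); use RegexTokenizer for "
                "pre-segmented or synthetic text"
            ) from exc
        self._tagger = fugashi.Tagger(tagger_args)  # pragma: no cover

    def __call__(self, text: str) -> list[str]:  # pragma: no cover
        return [w.surface for w in self._tagger(text)]


@dataclass
class FilterReport:
    """Stage-by-stage record counts with per-reason removal tallies.

    Counts reconcile: at every stage, the input count equals the output count
    plus the removals attributed to that stage.
    """

    n_input: int
    n_after_keyword: int | None = None
    n_after_dedup: int | None = None
    n_after_validity: int | None = None
    n_after_tokenize: int | None = None
    removal_counts: dict[str, int] = field(default_factory=dict)

    def add_removals(self, counts: dict[str, int]) -> None:
        for reason, n in counts.items():
            self.removal_counts[reason] = self.removal_counts.get(reason, 0) + n

    def n_output(self) -> int:
        for n in (
            self.n_after_tokenize,
            self.n_after_validity,
            self.n_after_dedup,
            self.n_after_keyword,
        ):
            if n is not None:
                return n
        return self.n_input

    def conserved(self) -> bool:
        return self.n_input == self.n_output() + sum(self.removal_counts.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_keyword": self.n_after_keyword,
            "n_after_dedup": self.n_after_dedup,
            "n_after_validity": self.n_after_validity,
            "n_after_tokenize": self.n_after_tokenize,
            "removal_counts": dict(self.removal_counts),
        }


def filter_keywords(
    posts: Sequence[RawPost], keywords: Iterable[str]
) -> list[RawPost]:
    """Retain posts whose text contains at least one keyword as a substring.

    Matching is case-insensitive (casefolded), emulating a vendor-level
    keyword query.  Order is preserved.
    """
    kws = [k.casefold() for k in keywords]
    if not kws:
        raise ValueError("keyword set must be non-empty")
    return [p for p in posts if any(k in p.text.casefold() for k in kws)]


_ws = re.compile(r"\s+")


def _normalize_text(text: str) -> str:
    """Unicode NFKC normalization plus whitespace collapse (dedup key)."""
    return _ws.sub(" ", unicodedata.normalize("NFKC", text)).strip()


def deduplicate(posts: Sequence[RawPost]) -> list[RawPost]:
    """Keep only the earliest post among those sharing (kind, normalized text).

    A tweet and a verbatim retweet of it both survive: the two kinds are
    analyzed as separate populations downstream.  Input order is preserved
    among survivors; timestamp ties keep the first occurrence.
    """
    best: dict[tuple[str, str], RawPost] = {}
    for p in posts:
        key = (p.kind, _normalize_text(p.text))
        cur = best.get(key)
        if cur is None or p.created_at < cur.created_at:
            best[key] = p
    keep = {id(p) for p in best.values()}
    return [p for p in posts if id(p) in keep]


_url = re.compile(r"\bhttps?://\S+|\bwww\.\S+", re.IGNORECASE)
_hashtag = re.compile(r"#\S+")
_mention = re.compile(r"@\w+")
_word_char = re.compile(r"\w", re.UNICODE)


def drop_invalid(
    posts: Sequence[RawPost],
) -> tuple[list[RawPost], FilterReport]:
    """Remove posts with no analyzable text content.

    A post is invalid when, after stripping URLs, ``#``-prefixed hashtag
    tokens and ``@``-mentions, no word character remains.  The removal reason
    records what the post consisted of: ``url_only``, ``hashtag_only``,
    ``mention_only``, ``symbol_only`` (only symbols/punctuation, possibly
    mixed with the above), or ``empty``.
    """
    survivors: list[RawPost] = []
    removed: Counter[str] = Counter()
    for p in posts:
        stripped = _mention.sub(" ", _hashtag.sub(" ", _url.sub(" ", p.text)))
        if _word_char.search(stripped):
            survivors.append(p)
            continue
        if not p.text.strip():
            reason = "empty"
        elif _url.search(p.text) and not _word_char.search(
            _url.sub(" ", p.text)
        ):
            reason = "url_only"
        elif _hashtag.search(p.text) and not _word_char.search(
            _hashtag.sub(" ", _url.sub(" ", p.text))
        ):
            reason = "hashtag_only"
        elif _mention.search(p.text):
            reason = "mention_only"
        else:
            reason = "symbol_only"
        removed[reason] += 1
    report = FilterReport(
        n_input=len(posts),
        n_after_validity=len(survivors),
        removal_counts=dict(removed),
    )
    return survivors, report


def day_of(ts: datetime, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS):
    """Calendar day of a timestamp under the study timezone.

    Timezone-aware instants are converted to the configured fixed offset;
    naive instants are taken as already study-local.
    """
    if ts.tzinfo is not None:
        ts = ts.astimezone(timezone(timedelta(hours=tz_offset_hours)))
    return ts.date()


def tokenize(
    posts: Sequence[RawPost],
    tokenizer: TokenizerInterface | None = None,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> tuple[list[CleanPost], FilterReport]:
    """Tokenize surviving posts into :class:`CleanPost` records.

    Posts yielding zero tokens, or on which the tokenizer raises, are dropped
    with reason ``untokenizable`` (the analogue of symbols a morphological
    analyzer cannot segment).
    """
    tokenizer = tokenizer or RegexTokenizer()
    clean: list[CleanPost] = []
    removed: Counter[str] = Counter()
    for p in posts:
        try:
            tokens = tuple(tokenizer(p.text))
        except Exception:
            tokens = ()
        if not tokens:
            removed["untokenizable"] += 1
            continue
        clean.append(
            CleanPost(
                id=p.id,
                kind=p.kind,
                created_at=p.created_at,
                text=p.text,
                tokens=tokens,
                day=day_of(p.created_at, tz_offset_hours),
            )
        )
    report = FilterReport(
        n_input=len(posts),
        n_after_tokenize=len(clean),
        removal_counts=dict(removed),
    )
    return clean, report


def preprocess_posts(
    posts: Sequence[RawPost],
    keywords: Iterable[str] | None = None,
    tokenizer: TokenizerInterface | None = None,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> tuple[list[CleanPost], FilterReport]:
    """Run the full preprocessing chain: keywords -> dedup -> validity -> tokens.

    ``keywords=None`` skips keyword filtering (synthetic corpora are already
    on-topic by construction).  Returns the surviving :class:`CleanPost`
    records and a reconciled :class:`FilterReport`.
    """
    report = FilterReport(n_input=len(posts))
    current: Sequence[RawPost] = list(posts)

    if keywords is not None:
        kept = filter_keywords(current, keywords)
        report.add_removals({"no_keyword": len(current) - len(kept)})
        current = kept
    report.n_after_keyword = len(current)

    deduped = deduplicate(current)
    report.add_removals({"duplicate": len(current) - len(deduped)})
    report.n_after_dedup = len(deduped)
    current = deduped

    valid, validity_report = drop_invalid(current)
    report.add_removals(validity_report.removal_counts)
    report.n_after_validity = len(valid)

    clean, token_report = tokenize(valid, tokenizer, tz_offset_hours)
    report.add_removals(token_report.removal_counts)
    report.n_after_tokenize = len(clean)
    return clean, report
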
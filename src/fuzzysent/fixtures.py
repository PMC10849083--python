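"""Small hand-written demonstration fixtures.

These are synthetic, hand-countable inputs used in documentation, tests and
the reproduction script to audit the preprocessing stage against known
removal counts.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from .types import RawPost


def preprocess_audit_fixture() -> tuple[list[RawPost], dict[str, int]]:
    """A 20-record corpus with a fully hand-counted cleaning outcome.

    Contents: 12 unique valid posts, 1 exact duplicate of a valid post,
    3 URL-only records (one of which duplicates another), 2 hashtag-only
    records (mutual duplicates), and 2 distinct symbol-only records.

    Expected outcome of the cleaning chain (dedup -> validity):
    3 removed as ``duplicate``, then 2 ``url_only``, 1 ``hashtag_only``,
    2 ``symbol_only`` — 12 survivors.  Returns (posts, expected removal
    counts).
    """
    t0 = datetime(2020, 3, 23, 12, 0, 0)

    def post(i: int, kind: str, text: str, minutes: int) -> RawPost:
        return RawPost(
            id=f"fx{i:02d}", kind=kind, created_at=t0 + timedelta(minutes=minutes),
            text=text,
        )

    valid_texts = [
        "corona case counts rising again today",
        "stay home and wash your hands",
        "new pneumonia coverage on the evening news",
        "grocery stores are crowded before the announcement",
        "working from home for the third week",
        "masks sold out at every pharmacy nearby",
        "the governor speaks at six tonight",
        "hospital staff deserve so much gratitude",
        "trains were almost empty this morning",
        "schools will stay closed through spring",
        "please check on your elderly neighbours",
        "small businesses need support right now",
    ]
    posts: list[RawPost] = []
    for i, text in enumerate(valid_texts):
        kind = "tweet" if i % 2 == 0 else "retweet"
        posts.append(post(i, kind, text, minutes=i))
    # exact duplicate of valid post 0 (same kind, later timestamp)
    posts.append(post(12, "tweet", valid_texts[0], minutes=30))
    # URL-only: A, A (duplicate), B
    posts.append(post(13, "tweet", "https://t.co/abc123", minutes=31))
    posts.append(post(14, "tweet", "https://t.co/abc123", minutes=32))
    posts.append(post(15, "retweet", "https://example.org/page?id=9", minutes=33))
    # hashtag-only: C, C (duplicate)
    posts.append(post(16, "tweet", "#COVID-19", minutes=34))
    posts.append(post(17, "tweet", "#COVID-19", minutes=35))
    # symbol-only: D, E (distinct)
    posts.append(post(18, "tweet", "!!!???", minutes=36))
    posts.append(post(19, "retweet", "...(^^)...", minutes=37))

    expected_removals = {
        "duplicate": 3,
        "url_only": 2,
        "hashtag_only": 1,
        "symbol_only": 2,
    }
    return posts, expected_removals
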
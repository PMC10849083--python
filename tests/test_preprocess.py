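"""Preprocessing: keyword filtering, dedup, validity, tokenization, conservation."""

from datetime import datetime, timezone

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fuzzysent import deduplicate, drop_invalid, filter_keywords, preprocess_posts, tokenize
from fuzzysent.fixtures import preprocess_audit_fixture
from fuzzysent.preprocess import RegexTokenizer, day_of
from fuzzysent.types import RawPost

from conftest import make_post


class TestFilterKeywords:
    def test_containment(self):
        posts = [make_post(0, "corona update")]
        assert filter_keywords(posts, {"corona"}) == posts

    def test_no_match_removed(self):
        assert filter_keywords([make_post(0, "no match here")], {"corona"}) == []

    def test_case_insensitive_latin(self):
        posts = [make_post(0, "COVID-19 news"), make_post(1, "covid-19 news")]
        assert len(filter_keywords(posts, {"Covid-19"})) == 2

    def test_fixture_counts(self):
        keywords = {"corona", "COVID-19", "new pneumonia"}
        posts = [
            make_post(0, "corona spreading fast"),
            make_post(1, "nice weather today"),
            make_post(2, "COVID-19 briefing at noon"),
            make_post(3, "cases of new pneumonia reported"),
            make_post(4, "totally unrelated text"),
            make_post(5, "CORONA measures announced"),
        ]
        kept = filter_keywords(posts, keywords)
        assert [p.id for p in kept] == ["t0", "t2", "t3", "t5"]

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            filter_keywords([make_post(0, "x")], set())


class TestDeduplicate:
    def test_earlier_survives(self):
        a = make_post(0, "same text", minute=5)
        b = make_post(1, "same text", minute=1)
        assert deduplicate([a, b]) == [b]

    def test_kind_in_key(self):
        a = make_post(0, "same text", kind="tweet")
        b = make_post(1, "same text", kind="retweet")
        assert deduplicate([a, b]) == [a, b]

    def test_nfkc_and_whitespace_normalization(self):
        a = make_post(0, "ＣＯＶＩＤ  news", minute=0)  # fullwidth + double space
        b = make_post(1, "COVID news", minute=1)
        assert deduplicate([a, b]) == [a]

    def test_fixture_three_pairs(self):
        posts = [make_post(i, f"unique {i}", minute=i) for i in range(4)]
        posts += [
            make_post(4, "dup one", minute=4), make_post(5, "dup one", minute=5),
            make_post(6, "dup two", minute=6), make_post(7, "dup two", minute=7),
            make_post(8, "dup three", minute=8), make_post(9, "dup three", minute=9),
        ]
        assert len(deduplicate(posts)) == 7

    def test_idempotent(self):
        posts = [make_post(0, "a"), make_post(1, "a", minute=2), make_post(2, "b")]
        once = deduplicate(posts)
        assert deduplicate(once) == once


class TestDropInvalid:
    def test_url_only_removed(self):
        survivors, report = drop_invalid([make_post(0, "https://t.co/abc")])
        assert survivors == []
        assert report.removal_counts == {"url_only": 1}

    def test_residual_content_retained(self):
        posts = [make_post(0, "corona cases rising https://t.co/abc")]
        survivors, report = drop_invalid(posts)
        assert survivors == posts

    def test_hashtag_only_removed(self):
        survivors, report = drop_invalid([make_post(0, "#COVID-19")])
        assert survivors == []
        assert report.removal_counts == {"hashtag_only": 1}

    def test_symbol_only_and_empty(self):
        survivors, report = drop_invalid(
            [make_post(0, "!!! ???"), make_post(1, "   ")]
        )
        assert survivors == []
        assert report.removal_counts == {"symbol_only": 1, "empty": 1}

    def test_mention_only(self):
        survivors, report = drop_invalid([make_post(0, "@someone")])
        assert survivors == []
        assert report.removal_counts == {"mention_only": 1}

    def test_idempotent(self):
        posts = [make_post(0, "keep me"), make_post(1, "#tag")]
        once, _ = drop_invalid(posts)
        twice, rep2 = drop_invalid(once)
        assert twice == once and rep2.removal_counts == {}


class TestTokenize:
    def test_whitespace_tokens(self):
        clean, _ = tokenize([make_post(0, "a b c")])
        assert clean[0].tokens == ("a", "b", "c")

    def test_untokenizable_dropped(self):
        clean, report = tokenize([make_post(0, "...")])
        assert clean == []
        assert report.removal_counts == {"untokenizable": 1}

    def test_fixture_one_drop(self):
        posts = [make_post(i, f"word{i} more") for i in range(4)]
        posts.append(make_post(4, "***"))
        clean, report = tokenize(posts)
        assert len(clean) == 4
        assert report.removal_counts["untokenizable"] == 1

    def test_raising_tokenizer_drops_post(self):
        def bad(text):
            raise RuntimeError("boom")

        clean, report = tokenize([make_post(0, "fine text")], tokenizer=bad)
        assert clean == [] and report.removal_counts == {"untokenizable": 1}

    def test_day_binning_timezone(self):
        # 23:00 UTC on Mar 23 is 08:00 JST on Mar 24
        aware = RawPost(
            id="a", kind="tweet",
            created_at=datetime(2020, 3, 23, 23, 0, tzinfo=timezone.utc),
            text="x",
        )
        assert day_of(aware.created_at, 9.0).isoformat() == "2020-03-24"
        naive = make_post(0, "x")
        assert day_of(naive.created_at, 9.0) == naive.created_at.date()


posts_strategy = st.lists(
    st.builds(
        RawPost,
        id=st.uuids().map(str),
        kind=st.sampled_from(["tweet", "retweet"]),
        created_at=st.datetimes(
            min_value=datetime(2020, 3, 23), max_value=datetime(2020, 4, 21)
        ),
        text=st.text(max_size=40),
    ),
    max_size=30,
)


class TestPipelineProperties:
    @given(posts=posts_strategy)
    def test_conservation(self, posts):
        clean, report = preprocess_posts(posts, keywords=None)
        assert report.conserved()
        assert report.n_after_tokenize == len(clean)

    @given(posts=posts_strategy)
    def test_order_stability(self, posts):
        clean, _ = preprocess_posts(posts, keywords=None)
        surviving_ids = [c.id for c in clean]
        input_order = [p.id for p in posts if p.id in set(surviving_ids)]
        assert surviving_ids == input_order

    @given(posts=posts_strategy)
    def test_dedup_then_validity_idempotent(self, posts):
        once = deduplicate(posts)
        assert deduplicate(once) == once
        valid, _ = drop_invalid(once)
        again, rep = drop_invalid(valid)
        assert again == valid and sum(rep.removal_counts.values()) == 0

    def test_audit_fixture_counts(self):
        posts, expected = preprocess_audit_fixture()
        clean, report = preprocess_posts(posts)
        assert len(posts) == 20
        assert len(clean) == 12
        assert report.removal_counts == expected
        assert report.conserved()
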
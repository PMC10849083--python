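"""Daily aggregation, period split, Mann-Whitney tests and effect sizes."""

from datetime import date, datetime
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from fuzzysent import (
    SyntheticConfig,
    compare_polarity,
    compare_sentiments,
    daily_proportions,
    effect_size_r,
    mann_whitney,
    split_periods,
)
from fuzzysent.sentiment import SentimentCall
from fuzzysent.stats import comparisons_frame
from fuzzysent.synthetic import simulate_daily_table
from fuzzysent.types import SENTIMENTS, CleanPost


def make_clean(i, kind="tweet", day=date(2020, 3, 23)):
    return CleanPost(
        id=f"c{i}", kind=kind, created_at=datetime.combine(day, datetime.min.time()),
        text="x", tokens=("x",), day=day,
    )


def make_call(i, sentiment):
    return SentimentCall(
        post_id=f"c{i}", sentiment=sentiment,
        distances={s: (0.0 if s == sentiment else 1.0) for s in SENTIMENTS},
    )


def exact_mw_oracle(x, y):
    """Exhaustive rank-arrangement enumeration of the two-sided exact p-value.

    Enumerates all C(n1+n2, n1) placements of the first sample among the
    pooled ranks; U depends only on rank positions.  Two-sided p is
    2 * min-tail probability, capped at 1.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # tie-free by assumption
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for positions in combinations(range(n1 + n2), n1):
        r = sum(sorted(range(1, n1 + n2 + 1))[p] for p in positions)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    total = comb(n1 + n2, n1)
    p_low = np.sum(us <= obs_u) / total
    p_high = np.sum(us >= obs_u) / total
    return min(1.0, 2 * min(p_low, p_high))


class TestDailyProportions:
    def test_single_sentiment_day(self):
        posts = [make_clean(i) for i in range(10)]
        calls = [make_call(i, "joy") for i in range(10)]
        table = daily_proportions(calls, posts)
        joy = table[table["sentiment"] == "joy"]["proportion"].item()
        assert joy == 1.0
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_split_counts(self):
        posts = [make_clean(i) for i in range(4)]
        sentiments = ["joy", "joy", "anger", "trust"]
        calls = [make_call(i, s) for i, s in enumerate(sentiments)]
        table = daily_proportions(calls, posts).set_index("sentiment")
        assert table.loc["joy", "proportion"] == 0.5
        assert table.loc["anger", "proportion"] == 0.25
        assert table.loc["trust", "proportion"] == 0.25
        assert table.loc["disgust", "count"] == 0

    def test_proportions_sum_to_one_per_cell(self):
        rng = np.random.default_rng(0)
        posts, calls = [], []
        for i in range(200):
            day = date(2020, 3, 23 + int(rng.integers(0, 5)))
            kind = "tweet" if rng.random() < 0.4 else "retweet"
            posts.append(make_clean(i, kind=kind, day=day))
            calls.append(make_call(i, SENTIMENTS[rng.integers(0, 7)]))
        table = daily_proportions(calls, posts)
        sums = table.groupby(["day", "group"])["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_planted_mixture_recovered_within_binomial_error(self):
        cfg = SyntheticConfig(
            n_days=2, boundary_day=2, posts_per_day_tweet=5000,
            posts_per_day_retweet=0, rng_seed=8,
        )
        table = simulate_daily_table(cfg)
        p = 1 / 7
        se = np.sqrt(p * (1 - p) / 5000)
        for _, row in table.iterrows():
            assert abs(row["proportion"] - p) < 4 * se


class TestSplitPeriods:
    def make_table(self, n_days=30):
        cfg = SyntheticConfig(n_days=n_days, boundary_day=n_days // 2,
                              posts_per_day_tweet=50, posts_per_day_retweet=50,
                              rng_seed=1)
        return simulate_daily_table(cfg)

    def test_fifteen_fifteen(self):
        table = self.make_table(30)
        boundary = datetime(2020, 4, 7, 0, 0)  # day 16 of a Mar 23 start
        before, after = split_periods(table, boundary)
        assert before["day"].nunique() == 15
        assert after["day"].nunique() == 15

    def test_boundary_outside_span_rejected(self):
        table = self.make_table(10)
        with pytest.raises(ValueError, match="empty period"):
            split_periods(table, date(2019, 1, 1))

    def test_partition_property(self):
        table = self.make_table(12)
        before, after = split_periods(table, date(2020, 3, 28))
        assert set(before["day"]) | set(after["day"]) == set(table["day"])
        assert set(before["day"]) & set(after["day"]) == set()


class TestMannWhitney:
    def test_identical_samples_degenerate(self):
        res = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_total_separation_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements
        assert res.method == "exact"

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                res = mann_whitney(x, y, mode="exact")
                assert res.p_value == pytest.approx(exact_mw_oracle(x, y), abs=1e-12)

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie-free"):
            mann_whitney([1, 1, 2], [2, 3, 4], mode="exact")

    def test_normal_approx_close_to_exact(self):
        # exhaustive over tie-free samples with 5 <= n1, n2 <= 8 (the
        # continuity-corrected approximation is coarser below n = 5)
        rng = np.random.default_rng(4)
        for n1 in range(5, 9):
            for n2 in range(5, 9):
                for _ in range(5):
                    x, y = rng.normal(size=n1), rng.normal(size=n2)
                    p_exact = mann_whitney(x, y, mode="exact").p_value
                    p_norm = mann_whitney(x, y, mode="normal_approx").p_value
                    assert abs(p_exact - p_norm) <= 0.03

    def test_rank_statistic_scale_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12) + 0.5
        a = mann_whitney(x, y)
        b = mann_whitney(3.7 * x, 3.7 * y)
        assert (a.U, a.Z, a.p_value) == (b.U, b.Z, b.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestEffectSize:
    def test_zero_z(self):
        assert effect_size_r(0.0, 10) == 0.0

    def test_arithmetic(self):
        assert effect_size_r(2.0, 100) == pytest.approx(0.2)

    def test_shift_increases_r(self):
        rng = np.random.default_rng(6)
        rs_null, rs_shift = [], []
        for _ in range(20):
            x = rng.normal(size=15)
            y_null = rng.normal(size=15)
            y_shift = rng.normal(size=15) + 2.0
            rs_null.append(effect_size_r(mann_whitney(x, y_null).Z, 30))
            rs_shift.append(effect_size_r(mann_whitney(x, y_shift).Z, 30))
        assert np.mean(rs_shift) > np.mean(rs_null)


def shifted_config(shift=0.15, seed=0, posts=500):
    base = {s: 1 / 7 for s in SENTIMENTS}
    after_rt = dict(base)
    after_rt["joy"] += shift
    scale = (1 - after_rt["joy"]) / (1 - base["joy"])
    for s in SENTIMENTS:
        if s != "joy":
            after_rt[s] = base[s] * scale
    return SyntheticConfig(
        n_days=30, boundary_day=15, posts_per_day_tweet=posts,
        posts_per_day_retweet=posts,
        mixture_after={"tweet": base, "retweet": after_rt},
        rng_seed=seed,
    )


class TestComparisons:
    def make_periods(self, cfg):
        table = simulate_daily_table(cfg)
        from datetime import timedelta

        return split_periods(table, cfg.start_date + timedelta(days=cfg.boundary_day))

    def test_fourteen_rows(self):
        before, after = self.make_periods(shifted_config(shift=0.0, seed=1))
        rows = compare_sentiments(before, after)
        assert len(rows) == 14
        assert [(r.label, r.group) for r in rows] == [
            (s, g) for s in SENTIMENTS for g in ("tweet", "retweet")
        ]

    def test_planted_retweet_joy_shift_detected(self):
        before, after = self.make_periods(shifted_config(shift=0.15, seed=2))
        rows = {(r.label, r.group): r for r in compare_sentiments(before, after)}
        assert rows[("joy", "retweet")].p_value < 0.05
        assert rows[("joy", "tweet")].p_value > 0.05

    def test_polarity_sample_sizes(self):
        before, after = self.make_periods(shifted_config(shift=0.0, seed=3))
        rows = compare_polarity(before, after)
        assert len(rows) == 4
        sizes = {(r.label, r.period): (r.n1, r.n2) for r in rows}
        assert sizes[("positive", "before")] == (30, 30)
        assert sizes[("positive", "after")] == (30, 30)
        assert sizes[("negative", "before")] == (60, 60)
        assert sizes[("negative", "after")] == (60, 60)

    def test_holm_adjustment_monotone(self):
        before, after = self.make_periods(shifted_config(shift=0.1, seed=4))
        rows = compare_sentiments(before, after, correction="holm")
        assert all(r.p_adjusted >= r.p_value - 1e-12 for r in rows)

    def test_frame_shape(self):
        before, after = self.make_periods(shifted_config(shift=0.0, seed=5))
        frame = comparisons_frame(compare_polarity(before, after))
        assert list(frame["label"]) == ["positive", "positive", "negative", "negative"]
        assert {"U", "Z", "p_value", "r"} <= set(frame.columns)
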
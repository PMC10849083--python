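"""Before/after intervention statistics on daily sentiment proportions.

Sentiment calls are aggregated into a daily table of per-group sentiment
proportions (the statistical unit is one day).  The study window is split at
an intervention boundary into "before" and "after" periods, and two families
of two-sided Mann-Whitney U tests are run:

* per (sentiment, group): before vs after daily proportions (7 x 2 = 14
  tests);
* per (polarity, period): tweet vs retweet, pooling the sentiment-day
  observations of each polarity (positive = trust, joy; negative = anger,
  anxiety, disgust, sadness; surprise in neither pool) — 4 tests.

Days are treated as independent observations; no autocorrelation adjustment
is made.  No multiple-testing correction is applied by default; Holm
adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import FilterReport  # noqa: F401  (re-exported convenience)
from .sentiment import SentimentCall
from .types import (
    NEGATIVE_SENTIMENTS,
    POSITIVE_SENTIMENTS,
    POST_KINDS,
    SENTIMENTS,
    CleanPost,
)

MWMode = Literal["exact", "normal_approx", "auto"]


@dataclass(frozen=True)
class MWResult:
    """Two-sided Mann-Whitney U test result.

    ``U`` is the statistic for the first sample; ``Z`` is the tie-corrected,
    continuity-corrected normal deviate (reported even when the p-value came
    from exact enumeration, since the standardized deviate feeds the effect
    size r = |Z| / sqrt(N)).
    """

    U: float
    Z: float
    p_value: float
    method: str
    degenerate: bool = False


def _z_statistic(x: np.ndarray, y: np.ndarray, U: float) -> float:
    """Normal deviate for U with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    diff = U - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    return float((diff - cc) / np.sqrt(var))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: MWMode = "auto"
) -> MWResult:
    """Two-sided Mann-Whitney U test.

    ``auto`` uses exact enumeration of the rank-sum distribution when both
    samples have at most 8 observations and there are no ties, and the
    tie-corrected, continuity-corrected normal approximation otherwise.
    Identical constant samples are degenerate: p = 1 with the flag set.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MWResult(
            U=len(x) * len(y) / 2.0, Z=0.0, p_value=1.0, method="degenerate",
            degenerate=True,
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "exact" or (mode == "auto" and len(x) <= 8 and len(y) <= 8 and not has_ties):
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        U = float(res.statistic)
        return MWResult(U=U, Z=_z_statistic(x, y, U), p_value=float(res.pvalue),
                        method="exact")
    if mode not in ("auto", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    U = float(res.statistic)
    Z = _z_statistic(x, y, U)
    p = min(1.0, 2.0 * sps.norm.sf(abs(Z)))
    return MWResult(U=U, Z=Z, p_value=p, method="normal_approx")


def effect_size_r(Z: float, n_total: int) -> float:
    """Standardized Mann-Whitney effect size r = |Z| / sqrt(N)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return abs(Z) / np.sqrt(n_total)


def daily_proportions(
    calls: Sequence[SentimentCall], posts: Sequence[CleanPost]
) -> pd.DataFrame:
    """Aggregate sentiment calls into a day x group x sentiment table.

    Proportion = count of the sentiment / judged posts within (day, group).
    The grid is completed with zero-count rows for sentiments unseen on a
    judged (day, group); (day, group) cells with no judged post are simply
    absent.  Columns: day, group, sentiment, count, proportion.
    """
    meta = {p.id: p for p in posts}
    rows = []
    for call in calls:
        post = meta.get(call.post_id)
        if post is None:
            raise KeyError(f"call for unknown post id {call.post_id!r}")
        rows.append((post.day, post.kind, call.sentiment))
    if not rows:
        return pd.DataFrame(columns=["day", "group", "sentiment", "count", "proportion"])
    df = pd.DataFrame(rows, columns=["day", "group", "sentiment"])
    counts = (
        df.groupby(["day", "group", "sentiment"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cells = counts[["day", "group"]].drop_duplicates()
    grid = cells.merge(pd.DataFrame({"sentiment": SENTIMENTS}), how="cross")
    table = grid.merge(counts, on=["day", "group", "sentiment"], how="left")
    table["count"] = table["count"].fillna(0).astype(int)
    totals = table.groupby(["day", "group"], observed=True)["count"].transform("sum")
    table["proportion"] = table["count"] / totals
    order = {s: i for i, s in enumerate(SENTIMENTS)}
    table = table.sort_values(
        ["day", "group", "sentiment"], key=lambda c: c.map(order) if c.name == "sentiment" else c
    ).reset_index(drop=True)
    return table


def split_periods(
    table: pd.DataFrame, boundary: datetime | date
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the daily table at the boundary's calendar date.

    "Before" holds days strictly earlier than the boundary date; "after"
    holds the boundary date onward.  Raises if either side is empty.
    """
    bdate = boundary.date() if isinstance(boundary, datetime) else boundary
    days = pd.Series(table["day"].unique())
    before = table[table["day"] < bdate]
    after = table[table["day"] >= bdate]
    if before.empty or after.empty:
        span = (days.min(), days.max()) if len(days) else (None, None)
        raise ValueError(
            f"boundary {bdate} leaves an empty period (data span {span[0]}..{span[1]})"
        )
    return before.reset_index(drop=True), after.reset_index(drop=True)


@dataclass(frozen=True)
class PeriodComparison:
    """One Mann-Whitney comparison row.

    For sentiment tests, sample 1 / sample 2 are the before / after daily
    proportions of one (sentiment, group).  For polarity tests they are the
    tweet / retweet pooled sentiment-day proportions within one period.
    """

    label: str  # sentiment name, or "positive"/"negative"
    group: str  # "tweet"/"retweet", or "tweet_vs_retweet"
    period: str  # "before_vs_after", or "before"/"after"
    n1: int
    n2: int
    median1: float
    median2: float
    sd1: float
    sd2: float
    U: float
    Z: float
    p_value: float
    r: float
    degenerate: bool = False
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def comparisons_frame(comparisons: Sequence[PeriodComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


def _series(table: pd.DataFrame, group: str, sentiments: Sequence[str]) -> np.ndarray:
    sel = table[(table["group"] == group) & (table["sentiment"].isin(sentiments))]
    return sel.sort_values(["sentiment", "day"])["proportion"].to_numpy()


def _holm(comparisons: list[PeriodComparison]) -> list[PeriodComparison]:
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([c.p_value for c in comparisons], method="holm")[1]
    return [
        PeriodComparison(**{**c.to_dict(), "p_adjusted": float(a)})
        for c, a in zip(comparisons, adj)
    ]


def compare_sentiments(
    before: pd.DataFrame,
    after: pd.DataFrame,
    mode: MWMode = "auto",
    correction: Literal["holm"] | None = None,
) -> list[PeriodComparison]:
    """Before-vs-after tests for each of the 14 (sentiment, group) pairs.

    Each test compares the daily proportion samples of one sentiment within
    one group across the boundary; medians and SDs of the daily values per
    period are reported alongside U, Z, p and r.
    """
    out: list[PeriodComparison] = []
    for s in SENTIMENTS:
        for g in POST_KINDS:
            x = _series(before, g, [s])
            y = _series(after, g, [s])
            res = mann_whitney(x, y, mode=mode)
            out.append(
                PeriodComparison(
                    label=s, group=g, period="before_vs_after",
                    n1=len(x), n2=len(y),
                    median1=float(np.median(x)), median2=float(np.median(y)),
                    sd1=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                    sd2=float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
                    U=res.U, Z=res.Z, p_value=res.p_value,
                    r=effect_size_r(res.Z, len(x) + len(y)),
                    degenerate=res.degenerate,
                )
            )
    return _holm(out) if correction == "holm" else out


POLARITY_MAP: dict[str, tuple[str, ...]] = {
    "positive": POSITIVE_SENTIMENTS,
    "negative": NEGATIVE_SENTIMENTS,
}


def compare_polarity(
    before: pd.DataFrame,
    after: pd.DataFrame,
    mode: MWMode = "auto",
    polarity_map: dict[str, tuple[str, ...]] | None = None,
    correction: Literal["holm"] | None = None,
) -> list[PeriodComparison]:
    """Tweet-vs-retweet tests per (polarity, period) — four tests.

    Observations are pooled over (sentiment in polarity) x day, so with 15
    days per period the positive pool has 2 x 15 = 30 observations per group
    and the negative pool 4 x 15 = 60.
    """
    pmap = polarity_map or POLARITY_MAP
    out: list[PeriodComparison] = []
    for polarity, sentiments in pmap.items():
        for period_name, table in (("before", before), ("after", after)):
            x = _series(table, "tweet", sentiments)
            y = _series(table, "retweet", sentiments)
            res = mann_whitney(x, y, mode=mode)
            out.append(
                PeriodComparison(
                    label=polarity, group="tweet_vs_retweet", period=period_name,
                    n1=len(x), n2=len(y),
                    median1=float(np.median(x)), median2=float(np.median(y)),
                    sd1=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                    sd2=float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
                    U=res.U, Z=res.Z, p_value=res.p_value,
                    r=effect_size_r(res.Z, len(x) + len(y)),
                    degenerate=res.degenerate,
                )
            )
    return _holm(out) if correction == "holm" else out
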
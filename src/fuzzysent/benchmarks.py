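"""Validation benchmarks: simulation studies that exercise the whole method.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns measured quantities (agreement rates, error
bounds, rejection rates).  They back both the acceptance test suite and the
reproduction script; nothing here hard-codes an expected outcome.
"""

from __future__ import annotations

import dataclasses
from datetime import timedelta
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .embedding import EmbeddingConfig, train_cbow, vectorize_posts
from .fcm import FCMConfig, fcm_fit, fcm_objective, fcm_update_centroids, fcm_update_memberships
from .preprocess import preprocess_posts
from .sentiment import assign_many, build_sentiment_centroids
from .stats import compare_sentiments, mann_whitney, split_periods
from .synthetic import SyntheticConfig, generate_corpus, generate_dictionary, simulate_daily_table
from .types import SENTIMENTS


# ---------------------------------------------------------------------------
# fuzzy-c-means internals

def fcm_iteration_invariants(n_instances: int = 50, seed: int = 0) -> dict[str, float]:
    """Row-sum and monotonicity checks on random FCM instances.

    Re-runs the alternating updates step by step (n <= 200, d <= 10, c <= 7)
    and records the worst membership row-sum deviation after every iteration
    and the worst relative increase of the objective between iterations.
    """
    rng = np.random.default_rng(seed)
    worst_row_sum = 0.0
    worst_rel_increase = 0.0
    for _ in range(n_instances):
        c = int(rng.integers(2, 8))
        d = int(rng.integers(1, 11))
        n = int(rng.integers(c, 201))
        X = rng.normal(size=(n, d))
        U = rng.dirichlet(np.ones(c), size=n)
        prev_J = None
        for _ in range(40):
            V = fcm_update_centroids(X, U, 2.0)
            U_new = fcm_update_memberships(X, V, 2.0)
            J = fcm_objective(X, U_new, V, 2.0)
            worst_row_sum = max(worst_row_sum, float(np.abs(U_new.sum(1) - 1).max()))
            if prev_J is not None and prev_J > 0:
                worst_rel_increase = max(worst_rel_increase, (J - prev_J) / prev_J)
            delta = np.abs(U_new - U).max()
            U, prev_J = U_new, J
            if delta < 1e-5:
                break
    return {
        "membership_row_sum_max_error": worst_row_sum,
        "objective_max_relative_increase": worst_rel_increase,
    }


def _gaussian_blobs(rng: np.random.Generator, sigma: float = 0.2):
    """3 spherical Gaussian clusters, means 10 sigma apart (equilateral)."""
    means = np.array([[0.0, 0.0], [10 * sigma, 0.0],
                      [5 * sigma, 5 * sigma * np.sqrt(3)]])
    labels = np.repeat(np.arange(3), 100)
    X = means[labels] + rng.normal(scale=sigma, size=(300, 2))
    return X, labels, means


def _best_agreement(pred: np.ndarray, truth: np.ndarray, k: int) -> float:
    conf = np.zeros((k, k))
    for a, b in zip(truth, pred):
        conf[a, b] += 1
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(truth))


def fcm_vs_kmeans_oracle(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """FCM against a k-means reference on well-separated Gaussian clusters.

    Reports the worst hardened-label agreement with scikit-learn's k-means
    and the worst distance of a recovered centroid from its true mean, over
    ``n_seeds`` independent replicates.
    """
    from sklearn.cluster import KMeans

    min_agreement = 1.0
    max_centroid_err = 0.0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        X, truth, means = _gaussian_blobs(rng)
        sub_seed = int(rng.integers(2**31))
        part = fcm_fit(X, FCMConfig(c=3, m=2.0, seed=sub_seed))
        km = KMeans(n_clusters=3, n_init=10, random_state=sub_seed % (2**31)).fit(X)
        agreement = _best_agreement(part.hard_labels(), km.labels_, 3)
        min_agreement = min(min_agreement, agreement)
        # match each FCM centroid to its nearest true mean
        d = np.linalg.norm(part.V[:, None, :] - means[None, :, :], axis=2)
        r, c = linear_sum_assignment(d)
        max_centroid_err = max(max_centroid_err, float(d[r, c].max()))
    return {
        "kmeans_label_agreement_min": min_agreement,
        "centroid_recovery_max_error": max_centroid_err,
    }


def kmeans_limit_membership(seed: int = 0) -> float:
    """Minimum over points of the maximal membership with m = 1 + 1e-6."""
    rng = np.random.default_rng(seed)
    X, _, _ = _gaussian_blobs(rng)
    part = fcm_fit(X, FCMConfig(c=3, m=1 + 1e-6, seed=seed))
    return float(part.U.max(axis=1).min())


def membership_worked_example_error() -> float:
    """|computed - hand value| for x=0, centroids {-1, +2}, m=2 -> (4/5, 1/5)."""
    U = fcm_update_memberships(np.array([[0.0]]), np.array([[-1.0], [2.0]]), 2.0)
    return float(np.abs(U[0] - np.array([0.8, 0.2])).max())


# ---------------------------------------------------------------------------
# Mann-Whitney

def _exact_enumeration_p(n1: int, n2: int, obs_u: float) -> float:
    """Two-sided exact p by enumerating all rank arrangements (tie-free)."""
    us = []
    for pos in combinations(range(n1 + n2), n1):
        rank_sum = sum(p + 1 for p in pos)
        us.append(rank_sum - n1 * (n1 + 1) / 2)
    us = np.array(us)
    total = comb(n1 + n2, n1)
    p_low = float((us <= obs_u).sum()) / total
    p_high = float((us >= obs_u).sum()) / total
    return min(1.0, 2 * min(p_low, p_high))


def mw_exact_vs_enumeration(seed: int = 0, reps_per_size: int = 3) -> float:
    """Worst |p - enumeration oracle p| over all tie-free n1, n2 <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n1 in range(1, 7):
        for n2 in range(1, 7):
            for _ in range(reps_per_size):
                x, y = rng.normal(size=n1), rng.normal(size=n2)
                res = mann_whitney(x, y, mode="exact")
                worst = max(worst, abs(res.p_value - _exact_enumeration_p(n1, n2, res.U)))
    return worst


def mw_type1_error_rate(
    n_reps: int = 10_000, n: int = 15, alpha: float = 0.05, seed: int = 0
) -> float:
    """Two-sided rejection rate under the null for n-vs-n normal samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if mann_whitney(x, y).p_value < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# end-to-end study

def study_config(seed: int = 0, planted_joy_shift: float = 0.15) -> SyntheticConfig:
    """The synthetic study design: 30 days split 15/15, 500 posts/day/group,
    signal strength 0.9, 7 x 20 lexicon words, and (optionally) a planted
    increase of the retweet group's joy share after the boundary."""
    base = {s: 1 / 7 for s in SENTIMENTS}
    after_rt = dict(base)
    after_rt["joy"] += planted_joy_shift
    scale = (1 - after_rt["joy"]) / (1 - base["joy"])
    for s in SENTIMENTS:
        if s != "joy":
            after_rt[s] = base[s] * scale
    return SyntheticConfig(
        n_days=30, boundary_day=15,
        posts_per_day_tweet=500, posts_per_day_retweet=500,
        lexicon_size_per_sentiment=20, signal_strength=0.9,
        mixture_after={"tweet": base, "retweet": after_rt},
        rng_seed=seed,
    )


#: Compact embedding used for the synthetic benchmark (see the methods note
#: on fuzzy-c-means behavior in higher-dimensional embedding spaces).
BENCHMARK_EMBEDDING = EmbeddingConfig(dim=6, window=5, epochs=3, negative=5, min_count=1)


def end_to_end_recovery(seed: int = 0, planted_joy_shift: float = 0.15) -> dict[str, float]:
    """Full pipeline on the synthetic study; measures label recovery.

    Generates the corpus, preprocesses, trains CBOW, fits FCM sentiment
    centroids, assigns every post, and compares the calls against the planted
    truth.  Also runs the before/after comparison and reports the p-value of
    the retweet-group joy test.
    """
    cfg = study_config(seed, planted_joy_shift)
    dictionary = generate_dictionary(cfg)
    corpus = generate_corpus(cfg, dictionary)
    clean, _ = preprocess_posts(corpus.posts)
    emb = train_cbow(
        clean,
        dataclasses.replace(BENCHMARK_EMBEDDING, seed=seed + 1),
        extra_vocabulary=dictionary.all_words(),
    )
    centroids, _ = build_sentiment_centroids(
        dictionary, emb, FCMConfig(c=7, m=2.0, seed=seed + 2)
    )
    docs, unjudged = vectorize_posts(clean, emb)
    calls = assign_many(docs, centroids)
    truth = corpus.true_sentiment
    accuracy = float(np.mean([truth[c.post_id] == c.sentiment for c in calls]))

    from .stats import daily_proportions

    table = daily_proportions(calls, clean)
    boundary = cfg.start_date + timedelta(days=cfg.boundary_day)
    before, after = split_periods(table, boundary)
    rows = {(r.label, r.group): r for r in compare_sentiments(before, after)}
    return {
        "recovery_accuracy": accuracy,
        "judged_fraction": len(calls) / len(clean),
        "joy_retweet_p": rows[("joy", "retweet")].p_value,
    }


def shift_detection_power(
    n_reps: int = 100, seed: int = 0, planted_joy_shift: float = 0.15
) -> float:
    """Fraction of replicates declaring the planted retweet-joy shift at P<.05.

    Replicates draw day-level sentiment counts directly from the study
    mixtures (the perfect-recovery limit of the pipeline, which the
    end-to-end run attains) and run the full 14-test comparison.
    """
    detected = 0
    root = np.random.SeedSequence([seed, 101])
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        cfg = study_config(0, planted_joy_shift)
        table = simulate_daily_table(cfg, rng)
        boundary = cfg.start_date + timedelta(days=cfg.boundary_day)
        before, after = split_periods(table, boundary)
        rows = {(r.label, r.group): r for r in compare_sentiments(before, after)}
        if rows[("joy", "retweet")].p_value < 0.05:
            detected += 1
    return detected / n_reps


def null_rejection_rates(n_reps: int = 100, seed: int = 0) -> dict[str, object]:
    """Per-test and pooled rejection rates with no planted shift.

    Returns the pooled rate over 14 tests x replicates and the per-test
    rejection counts (keyed "sentiment/group").
    """
    counts: dict[str, int] = {
        f"{s}/{g}": 0 for s in SENTIMENTS for g in ("tweet", "retweet")
    }
    root = np.random.SeedSequence([seed, 202])
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        cfg = study_config(0, planted_joy_shift=0.0)
        table = simulate_daily_table(cfg, rng)
        boundary = cfg.start_date + timedelta(days=cfg.boundary_day)
        before, after = split_periods(table, boundary)
        for r in compare_sentiments(before, after):
            if r.p_value < 0.05:
                counts[f"{r.label}/{r.group}"] += 1
    pooled = sum(counts.values()) / (n_reps * 14)
    return {"pooled_rate": pooled, "per_test_counts": counts, "n_reps": n_reps}
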
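"""Sentiment centroids from fuzzy-clustered lexicon words, and post labeling.

The seven emotion categories are given geometric form by clustering the
embedded dictionary words with fuzzy c-means (c = 7) and matching each
cluster to the emotion whose words it best absorbs (an assignment problem on
total membership mass).  A post is then labeled with the emotion whose
centroid lies at the shortest Euclidean distance from the post's document
vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .embedding import DocVector, WordEmbedding
from .fcm import FCMConfig, FuzzyPartition, fcm_fit
from .types import SENTIMENTS, SentimentDictionary


@dataclass(frozen=True)
class SentimentCentroids:
    """Seven labeled centroid vectors plus the cluster->sentiment bijection."""

    centroids: Mapping[str, np.ndarray]
    cluster_map: Mapping[int, str]

    def __post_init__(self) -> None:
        if set(self.centroids) != set(SENTIMENTS):
            raise ValueError("centroids must cover exactly the 7 sentiment labels")
        if sorted(self.cluster_map.values()) != sorted(SENTIMENTS):
            raise ValueError("cluster_map must be a bijection onto the 7 labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return SENTIMENTS

    def matrix(self) -> np.ndarray:
        """Centroids stacked in canonical label order, shape (7, d)."""
        return np.stack([np.asarray(self.centroids[s]) for s in SENTIMENTS])


@dataclass(frozen=True)
class SentimentCall:
    """One post's sentiment assignment with all seven distances."""

    post_id: str
    sentiment: str
    distances: Mapping[str, float]

    def __post_init__(self) -> None:
        dmin = min(self.distances.values())
        if self.distances[self.sentiment] > dmin + 1e-12:
            raise ValueError("assigned sentiment must attain the minimum distance")


def embed_dictionary(
    dictionary: SentimentDictionary, embedding: WordEmbedding
) -> tuple[list[str], np.ndarray]:
    """Vectors for all dictionary words, rows aligned with ``dictionary.all_words()``.

    Every dictionary word must be in the embedding vocabulary (the training
    step guarantees this by appending missing words as pseudo-documents).
    """
    words = dictionary.all_words()
    missing = [w for w in words if w not in embedding]
    if missing:
        raise ValueError(
            f"{len(missing)} dictionary words missing from the embedding "
            f"(first few: {missing[:5]}); train with extra_vocabulary"
        )
    return words, np.stack([embedding[w] for w in words])


def map_clusters_to_sentiments(
    partition: FuzzyPartition,
    dictionary: SentimentDictionary,
    embedding: WordEmbedding,
) -> SentimentCentroids:
    """Match FCM clusters to sentiments and return labeled centroids.

    ``partition`` must have been fitted with c = 7 on the dictionary-word
    vectors in ``dictionary.all_words()`` row order.  The bijection maximizes
    the total membership mass of each sentiment's words in its matched
    cluster, solved exactly as a linear assignment problem.
    """
    words, _ = embed_dictionary(dictionary, embedding)
    if partition.c != len(SENTIMENTS):
        raise ValueError(f"partition has c={partition.c}, expected {len(SENTIMENTS)}")
    if partition.n != len(words):
        raise ValueError(
            f"partition fitted on {partition.n} points but the dictionary has "
            f"{len(words)} words"
        )
    # score[s, t] = total membership of sentiment s's words in cluster t
    score = np.zeros((len(SENTIMENTS), partition.c))
    row = 0
    for si, s in enumerate(SENTIMENTS):
        k = len(dictionary.words[s])
        score[si] = partition.U[row : row + k].sum(axis=0)
        row += k
    s_idx, t_idx = linear_sum_assignment(-score)
    cluster_map = {int(t): SENTIMENTS[int(s)] for s, t in zip(s_idx, t_idx)}
    centroids = {
        label: partition.V[cluster].copy() for cluster, label in cluster_map.items()
    }
    return SentimentCentroids(centroids=centroids, cluster_map=cluster_map)


CentroidMode = Literal["fcm", "pruned_word_mean"]


def build_sentiment_centroids(
    dictionary: SentimentDictionary,
    embedding: WordEmbedding,
    fcm_config: FCMConfig | None = None,
    mode: CentroidMode = "fcm",
    membership_threshold: float = 0.5,
) -> tuple[SentimentCentroids, FuzzyPartition]:
    """Fit FCM (c = 7) on the embedded dictionary and build labeled centroids.

    ``mode="fcm"`` (default) uses the matched FCM centroids directly.
    ``mode="pruned_word_mean"`` instead prunes each lexicon to the words whose
    membership in the matched cluster is at least ``membership_threshold``
    and takes the plain mean of the surviving words' vectors — a
    dictionary-reduction reading of the same procedure; a lexicon where no
    word passes the threshold falls back to all its words.
    """
    if fcm_config is None:
        fcm_config = FCMConfig(c=len(SENTIMENTS))
    if fcm_config.c != len(SENTIMENTS):
        raise ValueError("sentiment clustering requires c = 7")
    words, X = embed_dictionary(dictionary, embedding)
    partition = fcm_fit(X, fcm_config)
    centroids = map_clusters_to_sentiments(partition, dictionary, embedding)
    if mode == "fcm":
        return centroids, partition
    if mode != "pruned_word_mean":
        raise ValueError(f"unknown centroid mode {mode!r}")
    label_to_cluster = {s: t for t, s in centroids.cluster_map.items()}
    pruned: dict[str, np.ndarray] = {}
    row = 0
    for s in SENTIMENTS:
        k = len(dictionary.words[s])
        rows = np.arange(row, row + k)
        row += k
        memb = partition.U[rows, label_to_cluster[s]]
        keep = rows[memb >= membership_threshold]
        if keep.size == 0:
            keep = rows
        pruned[s] = X[keep].mean(axis=0)
    return (
        SentimentCentroids(centroids=pruned, cluster_map=centroids.cluster_map),
        partition,
    )


def assign_sentiment(doc: DocVector, centroids: SentimentCentroids) -> SentimentCall:
    """Label one post by the nearest sentiment centroid (Euclidean).

    Exact ties resolve to the label earliest in canonical order
    (anger, anxiety, disgust, sadness, surprise, trust, joy).
    """
    M = centroids.matrix()
    d = np.linalg.norm(M - np.asarray(doc.vector), axis=1)
    best = int(np.argmin(d))  # argmin takes the first minimum: canonical tie-break
    return SentimentCall(
        post_id=doc.post_id,
        sentiment=SENTIMENTS[best],
        distances={s: float(d[i]) for i, s in enumerate(SENTIMENTS)},
    )


def assign_many(
    docs: Sequence[DocVector], centroids: SentimentCentroids
) -> list[SentimentCall]:
    """Vectorized nearest-centroid assignment for many posts."""
    if not docs:
        return []
    M = centroids.matrix()
    X = np.stack([np.asarray(d.vector) for d in docs])
    d2 = ((X[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    best = d.argmin(axis=1)
    return [
        SentimentCall(
            post_id=doc.post_id,
            sentiment=SENTIMENTS[int(b)],
            distances={s: float(row[i]) for i, s in enumerate(SENTIMENTS)},
        )
        for doc, b, row in zip(docs, best, d)
    ]
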
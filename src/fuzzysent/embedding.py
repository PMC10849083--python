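"""Continuous bag-of-words (CBOW) word embeddings and document vectors.

Implements a compact CBOW trainer with negative sampling: for each position
in the token stream, the mean of the context words' input vectors predicts
the center word against ``negative`` sampled noise words drawn from the
unigram distribution raised to the 3/4 power.  Training is mini-batched
numpy, single-threaded, and fully deterministic given the seed — a property
the downstream pipeline relies on for reproducibility.

Document vectors are mean-pooled word vectors; a document none of whose
tokens are in the vocabulary is *unjudgeable* (returned as ``None``), the
distinguished outcome propagated, not an error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .types import CleanPost


@dataclass
class EmbeddingConfig:
    """CBOW hyperparameters.

    dim:
        Vector dimension (>= 2).
    window:
        Context radius; the context of a position is up to ``window`` tokens
        on each side.
    epochs:
        Passes over the corpus.
    negative:
        Noise words per positive example.
    min_count:
        Minimum corpus frequency for a word to enter the vocabulary.
    seed:
        Seeds initialization, shuffling and negative sampling.
    alpha / min_alpha:
        Initial learning rate, decayed linearly to ``min_alpha`` over
        training.
    """

    dim: int = 100
    window: int = 5
    epochs: int = 5
    negative: int = 5
    min_count: int = 1
    seed: int = 0
    alpha: float = 0.025
    min_alpha: float = 1e-4
    batch_size: int = 512

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")


class WordEmbedding:
    """Vocabulary plus one d-dimensional vector per word."""

    def __init__(self, words: Sequence[str], vectors: np.ndarray) -> None:
        if len(words) != vectors.shape[0]:
            raise ValueError("one vector per word required")
        if not np.isfinite(vectors).all():
            raise ValueError("vectors must be finite")
        self.words: list[str] = list(words)
        self.vectors: np.ndarray = np.asarray(vectors, dtype=np.float64)
        self.index: dict[str, int] = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[self.index[word]]

    def __len__(self) -> int:
        return len(self.words)

    def save_word2vec(self, path: str | Path) -> None:
        """Persist in the word2vec text format ('n dim' header, then rows)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, v in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "WordEmbedding":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(words) != n:
            raise ValueError(f"header promised {n} words, found {len(words)}")
        return cls(words, np.array(rows, dtype=np.float64))


@dataclass(frozen=True)
class DocVector:
    """Mean-pooled document vector for one post."""

    post_id: str
    vector: np.ndarray
    n_known_tokens: int

    def __post_init__(self) -> None:
        if self.n_known_tokens < 1:
            raise ValueError("a DocVector requires at least one known token")


#: Cap on the effective number of within-batch repeats of one embedding row;
#: keeps the implied per-row learning rate bounded on small vocabularies.
_ROW_UPDATE_CAP = 16.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_cbow(
    corpus: Sequence[CleanPost] | Sequence[Sequence[str]],
    config: EmbeddingConfig,
    extra_vocabulary: Iterable[str] = (),
) -> WordEmbedding:
    """Train CBOW word vectors on a tokenized corpus.

    ``corpus`` may be :class:`CleanPost` records or bare token sequences.
    ``extra_vocabulary`` words (e.g. emotion-lexicon entries absent from the
    corpus) are appended as pseudo-documents so they are guaranteed a vector
    in the same space; lacking context they keep their initialization, which
    downstream code treats like any other embedded word.

    Deterministic: identical corpus, config and extra vocabulary give
    identical vectors.
    """
    sentences: list[Sequence[str]] = [
        p.tokens if isinstance(p, CleanPost) else list(p) for p in corpus
    ]
    if not sentences:
        raise ValueError("corpus must be non-empty")
    # pseudo-documents guarantee vocabulary membership past the min_count gate
    for w in extra_vocabulary:
        sentences.append([w] * config.min_count)

    counts = Counter(t for s in sentences for t in s)
    vocab = sorted(
        (w for w, c in counts.items() if c >= config.min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab:
        raise ValueError("vocabulary is empty after applying min_count")
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    # flattened (center, padded context) training examples
    w2 = 2 * config.window
    centers: list[np.ndarray] = []
    ctxs: list[np.ndarray] = []
    for s in sentences:
        idx = np.array([index[t] for t in s if t in index], dtype=np.int64)
        n = idx.size
        if n < 2:
            continue
        ctx = np.full((n, w2), V, dtype=np.int64)  # V = pad row
        for off in range(1, config.window + 1):
            ctx[off:, config.window - off] = idx[:-off]
            ctx[:-off, config.window + off - 1] = idx[off:]
        centers.append(idx)
        ctxs.append(ctx)
    rng = np.random.default_rng(config.seed)
    W_in = (rng.random((V + 1, config.dim)) - 0.5) / config.dim
    W_in[V] = 0.0
    W_out = np.zeros((V, config.dim))

    if centers:
        center_arr = np.concatenate(centers)
        ctx_arr = np.vstack(ctxs)
        mask = (ctx_arr != V).astype(np.float64)
        n_ctx = mask.sum(axis=1)

        freq = np.array([counts[w] for w in vocab], dtype=np.float64)
        noise = freq**0.75
        noise_cdf = np.cumsum(noise / noise.sum())

        N = center_arr.size
        B = config.batch_size
        n_batches_total = config.epochs * max(1, -(-N // B))
        batch_no = 0
        for _ in range(config.epochs):
            order = rng.permutation(N)
            for start in range(0, N, B):
                sel = order[start : start + B]
                b = sel.size
                lr = config.alpha + (config.min_alpha - config.alpha) * (
                    batch_no / max(1, n_batches_total - 1)
                )
                batch_no += 1
                ctx_b = ctx_arr[sel]
                m_b = mask[sel]
                h = (W_in[ctx_b] * m_b[:, :, None]).sum(axis=1) / n_ctx[sel][:, None]
                neg = np.searchsorted(
                    noise_cdf, rng.random((b, config.negative))
                ).astype(np.int64)
                targets = np.concatenate([center_arr[sel][:, None], neg], axis=1)
                labels = np.zeros((b, config.negative + 1))
                labels[:, 0] = 1.0
                out_vecs = W_out[targets]
                scores = np.einsum("bkd,bd->bk", out_vecs, h)
                g = (labels - _sigmoid(scores)) * lr
                # rows repeated within a batch accumulate their gradients at
                # one parameter point; cap the effective repetition so the
                # implied per-row step stays bounded (sequential SGD would
                # re-evaluate the sigmoid between repeats and self-saturate)
                cap = _ROW_UPDATE_CAP
                delta_out = np.zeros_like(W_out)
                np.add.at(delta_out, targets, g[:, :, None] * h[:, None, :])
                cnt_out = np.bincount(targets.ravel(), minlength=V).astype(np.float64)
                np.maximum(cnt_out, 1.0, out=cnt_out)
                W_out += delta_out * np.minimum(1.0, cap / cnt_out)[:, None]
                h_grad = np.einsum("bk,bkd->bd", g, out_vecs) / n_ctx[sel][:, None]
                delta_in = np.zeros_like(W_in)
                np.add.at(delta_in, ctx_b, h_grad[:, None, :] * m_b[:, :, None])
                cnt_in = np.bincount(
                    ctx_b[m_b > 0].ravel(), minlength=V + 1
                ).astype(np.float64)
                np.maximum(cnt_in, 1.0, out=cnt_in)
                W_in += delta_in * np.minimum(1.0, cap / cnt_in)[:, None]
                W_in[V] = 0.0

    return WordEmbedding(vocab, W_in[:V].copy())


Weighting = Literal["type_mean", "token_mean"]


def vectorize_document(
    tokens: Sequence[str],
    embedding: WordEmbedding,
    weighting: Weighting = "type_mean",
) -> tuple[np.ndarray | None, int]:
    """Mean-pool token vectors into one document vector.

    ``type_mean`` (default) averages each distinct in-vocabulary word once;
    ``token_mean`` weights words by their occurrence count.  Returns
    ``(vector, n_known_tokens)``; the vector is ``None`` — the document is
    unjudgeable — when no token is in the vocabulary.
    """
    known = [t for t in tokens if t in embedding]
    if not known:
        return None, 0
    if weighting == "type_mean":
        idx = sorted({embedding.index[t] for t in known})
    elif weighting == "token_mean":
        idx = [embedding.index[t] for t in known]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return embedding.vectors[idx].mean(axis=0), len(known)


def vectorize_posts(
    posts: Sequence[CleanPost],
    embedding: WordEmbedding,
    weighting: Weighting = "type_mean",
) -> tuple[list[DocVector], list[str]]:
    """Vectorize many posts; returns (judgeable DocVectors, unjudgeable ids)."""
    docs: list[DocVector] = []
    unjudgeable: list[str] = []
    for p in posts:
        vec, n_known = vectorize_document(p.tokens, embedding, weighting)
        if vec is None:
            unjudgeable.append(p.id)
        else:
            docs.append(DocVector(post_id=p.id, vector=vec, n_known_tokens=n_known))
    return docs, unjudgeable
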
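"""Readers and writers for the pipeline's on-disk formats.

Posts travel as JSON Lines ({"id", "kind", "created_at", "text"}, plus
"tokens" once tokenized); lexicons and truth labels as two-column CSV;
centroids and reports as JSON.  All files are UTF-8 text.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sentiment import SentimentCall, SentimentCentroids
from .types import SENTIMENTS, CleanPost, RawPost, SentimentDictionary


def write_posts_jsonl(posts: Iterable[RawPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "kind": p.kind,
                        "created_at": p.created_at.isoformat(),
                        "text": p.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_posts_jsonl(path: str | Path) -> list[RawPost]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"posts file not found: {path}")
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            posts.append(
                RawPost(
                    id=str(rec["id"]),
                    kind=rec["kind"],
                    created_at=datetime.fromisoformat(rec["created_at"]),
                    text=rec["text"],
                )
            )
    return posts


def write_clean_posts_jsonl(posts: Iterable[CleanPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "kind": p.kind,
                        "created_at": p.created_at.isoformat(),
                        "text": p.text,
                        "tokens": list(p.tokens),
                        "day": p.day.isoformat(),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_clean_posts_jsonl(path: str | Path) -> list[CleanPost]:
    from datetime import date

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clean posts file not found: {path}")
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            posts.append(
                CleanPost(
                    id=str(rec["id"]),
                    kind=rec["kind"],
                    created_at=datetime.fromisoformat(rec["created_at"]),
                    text=rec["text"],
                    tokens=tuple(rec["tokens"]),
                    day=date.fromisoformat(rec["day"]),
                )
            )
    return posts


def write_dictionary_csv(dictionary: SentimentDictionary, path: str | Path) -> None:
    rows = [(s, w) for s in SENTIMENTS for w in dictionary.words[s]]
    pd.DataFrame(rows, columns=["sentiment", "word"]).to_csv(path, index=False)


def read_dictionary_csv(path: str | Path) -> SentimentDictionary:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dictionary file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    words = {
        s: tuple(df.loc[df["sentiment"] == s, "word"]) for s in df["sentiment"].unique()
    }
    return SentimentDictionary(words=words)


def write_labels_csv(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["id", "sentiment"]).to_csv(
        path, index=False
    )


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["id"], df["sentiment"]))


def write_centroids_json(centroids: SentimentCentroids, path: str | Path) -> None:
    payload = {
        "cluster_map": {str(k): v for k, v in centroids.cluster_map.items()},
        "centroids": {s: np.asarray(v).tolist() for s, v in centroids.centroids.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_centroids_json(path: str | Path) -> SentimentCentroids:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SentimentCentroids(
        centroids={s: np.array(v, dtype=float) for s, v in payload["centroids"].items()},
        cluster_map={int(k): v for k, v in payload["cluster_map"].items()},
    )


def write_calls_csv(calls: Sequence[SentimentCall], path: str | Path) -> None:
    rows = [
        {"post_id": c.post_id, "sentiment": c.sentiment}
        | {f"dist_{s}": c.distances[s] for s in SENTIMENTS}
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> list[SentimentCall]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calls file not found: {path}")
    df = pd.read_csv(path, dtype={"post_id": str})
    return [
        SentimentCall(
            post_id=row["post_id"],
            sentiment=row["sentiment"],
            distances={s: float(row[f"dist_{s}"]) for s in SENTIMENTS},
        )
        for _, row in df.iterrows()
    ]


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")
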
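"""End-to-end orchestration: acquire -> preprocess -> embed -> model -> assign -> compare.

A :class:`RunConfig` names the input source (a posts file plus lexicon, or
the synthetic generator), the intervention boundary, and the hyperparameters
of every stage.  ``run_pipeline`` executes the stages in order, persists each
intermediate artifact under the output directory, and returns a
:class:`RunReport` reconciling record counts across stages.  One global seed
deterministically derives the sub-seed of every stochastic stage, so a
(config, seed) pair fully determines every output artifact.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Any, Literal, Mapping

from . import io as fio
from .embedding import EmbeddingConfig, train_cbow, vectorize_posts
from .fcm import FCMConfig
from .preprocess import (
    DEFAULT_TZ_OFFSET_HOURS,
    RegexTokenizer,
    TokenizerInterface,
    preprocess_posts,
)
from .sentiment import CentroidMode, assign_many, build_sentiment_centroids
from .stats import (
    MWMode,
    compare_polarity,
    compare_sentiments,
    comparisons_frame,
    daily_proportions,
    split_periods,
)
from .synthetic import SyntheticConfig, generate_corpus, generate_dictionary, inject_dirty_records
from .types import SENTIMENTS

logger = logging.getLogger("fuzzysent")

_SEED_MOD = 2**31


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage, the cause is chained."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full run configuration.

    Exactly one input source must be active: either ``synthetic`` or the
    (``posts_path``, ``dictionary_path``) pair.  ``boundary`` may be omitted
    in synthetic mode (derived from the generator's boundary day).
    """

    synthetic: SyntheticConfig | None = None
    posts_path: str | None = None
    dictionary_path: str | None = None
    keywords: list[str] | None = None  # None = skip keyword filtering
    boundary: datetime | date | None = None
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    fcm: FCMConfig = field(default_factory=lambda: FCMConfig(c=len(SENTIMENTS)))
    centroid_mode: CentroidMode = "fcm"
    membership_threshold: float = 0.5
    doc_weighting: Literal["type_mean", "token_mean"] = "type_mean"
    mw_mode: MWMode = "auto"
    correction: Literal["holm"] | None = None
    out_dir: str = "results"
    seed: int = 0

    def resolved_boundary(self) -> datetime | date:
        if self.boundary is not None:
            return self.boundary
        if self.synthetic is not None:
            return self.synthetic.start_date + timedelta(days=self.synthetic.boundary_day)
        raise ValueError("boundary is required when reading posts from a file")


def validate_config(config: RunConfig | Mapping[str, Any]) -> list[str]:
    """Return all configuration findings (empty list = valid); never mutates.

    Accepts either a built :class:`RunConfig` or a raw mapping of the shape
    used in YAML run files, in which case sub-config invariant violations
    (e.g. a fuzzifier not exceeding 1) are reported as findings rather than
    raised.
    """
    findings: list[str] = []
    if isinstance(config, Mapping):
        for key, cls in (
            ("synthetic", SyntheticConfig),
            ("embedding", EmbeddingConfig),
            ("fcm", FCMConfig),
        ):
            if key in config and config[key] is not None:
                try:
                    sub = config[key]
                    cls(**sub) if isinstance(sub, Mapping) else None
                except (TypeError, ValueError) as exc:
                    msg = str(exc)
                    if key == "fcm" and "fuzzifier" in msg:
                        msg = "fuzzifier must exceed 1"
                    findings.append(f"{key}: {msg}")
        has_synth = config.get("synthetic") is not None
        has_files = config.get("posts_path") is not None
        if has_synth == has_files:
            findings.append("exactly one of synthetic / posts_path must be active")
        if not has_synth and config.get("boundary") is None:
            findings.append("boundary is required when reading posts from a file")
        return findings

    has_synth = config.synthetic is not None
    has_files = config.posts_path is not None
    if has_synth == has_files:
        findings.append("exactly one of synthetic / posts_path must be active")
    if has_files:
        if config.dictionary_path is None:
            findings.append("dictionary_path is required with posts_path")
        if config.boundary is None:
            findings.append("boundary is required when reading posts from a file")
        if config.posts_path is not None and not Path(config.posts_path).exists():
            findings.append(f"posts file not found: {config.posts_path}")
        if config.dictionary_path is not None and not Path(config.dictionary_path).exists():
            findings.append(f"dictionary file not found: {config.dictionary_path}")
    if config.fcm.c != len(SENTIMENTS):
        findings.append(f"fcm.c must be {len(SENTIMENTS)} for the 7-sentiment model")
    if config.keywords is not None and len(config.keywords) == 0:
        findings.append("keyword list, when given, must be non-empty")
    return findings


def derive_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds from the global seed."""
    return {
        "synthetic": seed % _SEED_MOD,
        "embedding": (seed * 2654435761 + 1) % _SEED_MOD,
        "fcm": (seed * 2654435761 + 2) % _SEED_MOD,
    }


@dataclass
class RunReport:
    """Stage counts, effective parameters and artifact paths for one run."""

    params: dict[str, Any]
    stage_counts: dict[str, int] = field(default_factory=dict)
    removal_counts: dict[str, int] = field(default_factory=dict)
    judged_fraction: float | None = None
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(
    config: RunConfig, tokenizer: TokenizerInterface | None = None
) -> RunReport:
    """Execute the full analysis and persist every intermediate artifact.

    Artifacts written under ``config.out_dir``: posts.jsonl (synthetic mode),
    dictionary.csv, labels.csv (synthetic), clean_posts.jsonl,
    filter_report.json, embedding.txt, centroids.json, memberships.csv,
    calls.csv, daily_table.csv, sentiment_comparisons.{csv,json},
    polarity_comparisons.{csv,json}, run_report.json.
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid configuration: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    tokenizer = tokenizer or RegexTokenizer()
    report = RunReport(
        params={
            "seed": config.seed,
            "sub_seeds": seeds,
            "boundary": str(config.resolved_boundary()),
            "embedding": dataclasses.asdict(config.embedding),
            "fcm": dataclasses.asdict(config.fcm),
            "centroid_mode": config.centroid_mode,
            "doc_weighting": config.doc_weighting,
            "mw_mode": config.mw_mode,
            "keywords": config.keywords,
            "tz_offset_hours": config.tz_offset_hours,
        }
    )

    @_stage("acquire")
    def acquire():
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, rng_seed=seeds["synthetic"])
            report.params["synthetic"] = {
                **dataclasses.asdict(syn),
                "start_date": str(syn.start_date),
            }
            dictionary = generate_dictionary(syn)
            corpus = inject_dirty_records(generate_corpus(syn, dictionary), syn)
            fio.write_posts_jsonl(corpus.posts, out / "posts.jsonl")
            fio.write_labels_csv(corpus.true_sentiment, out / "labels.csv")
            posts = list(corpus.posts)
        else:
            posts = fio.read_posts_jsonl(config.posts_path)
            dictionary = fio.read_dictionary_csv(config.dictionary_path)
        fio.write_dictionary_csv(dictionary, out / "dictionary.csv")
        report.artifacts["dictionary"] = str(out / "dictionary.csv")
        return posts, dictionary

    posts, dictionary = acquire()
    report.stage_counts["input"] = len(posts)
    logger.info("acquired %d posts", len(posts))

    @_stage("preprocess")
    def do_preprocess():
        clean, frep = preprocess_posts(
            posts, config.keywords, tokenizer, config.tz_offset_hours
        )
        fio.write_clean_posts_jsonl(clean, out / "clean_posts.jsonl")
        fio.write_json(frep.to_dict(), out / "filter_report.json")
        report.artifacts["filter_report"] = str(out / "filter_report.json")
        return clean, frep

    clean, frep = do_preprocess()
    report.stage_counts["clean"] = len(clean)
    report.removal_counts = dict(frep.removal_counts)
    logger.info("preprocessing kept %d/%d posts", len(clean), len(posts))

    @_stage("embed")
    def do_embed():
        emb_cfg = dataclasses.replace(config.embedding, seed=seeds["embedding"])
        emb = train_cbow(clean, emb_cfg, extra_vocabulary=dictionary.all_words())
        emb.save_word2vec(out / "embedding.txt")
        report.artifacts["embedding"] = str(out / "embedding.txt")
        return emb

    embedding = do_embed()
    report.stage_counts["vocabulary"] = len(embedding)

    @_stage("build_model")
    def do_model():
        fcm_cfg = dataclasses.replace(config.fcm, seed=seeds["fcm"])
        centroids, partition = build_sentiment_centroids(
            dictionary,
            embedding,
            fcm_cfg,
            mode=config.centroid_mode,
            membership_threshold=config.membership_threshold,
        )
        fio.write_centroids_json(centroids, out / "centroids.json")
        import pandas as pd

        pd.DataFrame(
            partition.U,
            index=dictionary.all_words(),
            columns=[f"u_{t}" for t in range(partition.c)],
        ).rename_axis("word").to_csv(out / "memberships.csv")
        report.artifacts["centroids"] = str(out / "centroids.json")
        report.params["fcm_converged"] = partition.converged
        report.params["fcm_n_iter"] = partition.n_iter
        return centroids

    centroids = do_model()

    @_stage("assign")
    def do_assign():
        docs, unjudgeable = vectorize_posts(clean, embedding, config.doc_weighting)
        calls = assign_many(docs, centroids)
        fio.write_calls_csv(calls, out / "calls.csv")
        report.artifacts["calls"] = str(out / "calls.csv")
        return calls, unjudgeable

    calls, unjudgeable = do_assign()
    report.stage_counts["judged"] = len(calls)
    report.stage_counts["unjudgeable"] = len(unjudgeable)
    report.judged_fraction = len(calls) / len(clean) if clean else None

    @_stage("compare")
    def do_compare():
        table = daily_proportions(calls, clean)
        table.to_csv(out / "daily_table.csv", index=False)
        before, after = split_periods(table, config.resolved_boundary())
        sent_cmp = compare_sentiments(
            before, after, mode=config.mw_mode, correction=config.correction
        )
        pol_cmp = compare_polarity(
            before, after, mode=config.mw_mode, correction=config.correction
        )
        comparisons_frame(sent_cmp).to_csv(out / "sentiment_comparisons.csv", index=False)
        comparisons_frame(pol_cmp).to_csv(out / "polarity_comparisons.csv", index=False)
        fio.write_json([c.to_dict() for c in sent_cmp], out / "sentiment_comparisons.json")
        fio.write_json([c.to_dict() for c in pol_cmp], out / "polarity_comparisons.json")
        report.artifacts["daily_table"] = str(out / "daily_table.csv")
        report.artifacts["sentiment_comparisons"] = str(out / "sentiment_comparisons.csv")
        report.artifacts["polarity_comparisons"] = str(out / "polarity_comparisons.csv")
        return sent_cmp, pol_cmp

    do_compare()
    report.stage_counts["sentiment_tests"] = 14
    report.stage_counts["polarity_tests"] = 4
    fio.write_json(report.to_dict(), out / "run_report.json")
    report.artifacts["run_report"] = str(out / "run_report.json")
    return report
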
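from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from fuzzysent import SyntheticConfig, generate_corpus, generate_dictionary
from fuzzysent.types import RawPost

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_post(i: int, text: str, kind: str = "tweet", minute: int = 0) -> RawPost:
    return RawPost(
        id=f"t{i}", kind=kind, created_at=datetime(2020, 3, 23, 10, minute), text=text
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_days=6,
        boundary_day=3,
        posts_per_day_tweet=20,
        posts_per_day_retweet=40,
        lexicon_size_per_sentiment=5,
        filler_vocab_size=50,
        tokens_per_post=(4, 8),
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config, generate_dictionary(small_config))
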
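import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carevoice import CJSConfig, FeedbackItem, GeneratorConfig, PipelineConfig, Source
from carevoice.simulate import SourceProfile

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_item(i=0, org="H1", source=Source.rating_site, date=dt.date(2016, 6, 1),
              stars=4, text=None, is_repost=False, author_is_org=False):
    return FeedbackItem(
        item_id=f"it{i}", org_id=org, source=source, date=date, stars=stars,
        text=text, is_repost=is_repost, author_is_org=author_is_org,
    )


def random_items(n, rng, org_ids=("H1", "H2"), start=dt.date(2016, 1, 1), span_days=365):
    """A mixed synthetic feedback stream with random flags, for oracles."""
    items = []
    for i in range(n):
        items.append(
            FeedbackItem(
                item_id=f"r{i:05d}",
                org_id=org_ids[int(rng.integers(len(org_ids)))],
                source=list(Source)[int(rng.integers(3))],
                date=start + dt.timedelta(days=int(rng.integers(span_days))),
                stars=int(rng.integers(1, 6)),
                text=f"t{int(rng.integers(50))}",
                is_repost=bool(rng.uniform() < 0.2),
                author_is_org=bool(rng.uniform() < 0.1),
            )
        )
    return items


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_generator_config():
    """A scaled-down study configuration for fast pipeline-level tests."""
    return GeneratorConfig(
        n_trusts=12,
        hospitals_per_trust=2,
        period=(dt.date(2016, 3, 1), dt.date(2016, 8, 31)),
        seed=3,
    )


@pytest.fixture
def small_pipeline_config():
    return PipelineConfig(
        generator=GeneratorConfig(
            n_trusts=12, hospitals_per_trust=2,
            period=(dt.date(2016, 3, 1), dt.date(2016, 8, 31)),
        ),
        cjs=CJSConfig(),
        corpus_n=600,
        n_select_hospitals=8,
        n_select_trusts=4,
        seed=3,
    )
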
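"""Shared fixtures: the worked-example cascade and small simulated datasets."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from infocascade.models import Dataset, Post, RepostRecord, User
from infocascade.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

T0 = dt.datetime(2020, 3, 1, 10, 0)


def _min(minutes: int) -> dt.datetime:
    return T0 + dt.timedelta(minutes=minutes)


@pytest.fixture
def example_root() -> Post:
    return Post(post_id="A", author_id="userA", timestamp=T0, forwards=8)


@pytest.fixture
def example_reposts() -> list[RepostRecord]:
    """The nine-node example cascade, expressed as raw chain texts.

    B1, B2, B3 forward the root A; C1, C2, C3 forward B1; C4 forwards B3;
    D1 forwards C3. B1 is the busiest repost (3 onward forwards).
    """

    def rec(rid, ts, chain, forwards=0, likes=0):
        return RepostRecord(
            repost_id=rid,
            root_post_id="A",
            reposter_id=rid,
            timestamp=ts,
            chain_text=chain,
            forwards=forwards,
            likes=likes,
        )

    return [
        rec("B1", _min(10), "b1", forwards=3),
        rec("B2", _min(12), "b2"),
        rec("B3", _min(15), "b3", forwards=1),
        rec("C1", _min(30), "c1//@B1: b1"),
        rec("C2", _min(32), "c2//@B1: b1"),
        rec("C3", _min(35), "c3//@B1: b1", forwards=1),
        rec("C4", _min(40), "c4//@B3: b3"),
        rec("D1", _min(50), "d1//@C3: c3//@B1: b1"),
    ]


EXAMPLE_EDGES = {
    ("A", "B1"),
    ("A", "B2"),
    ("A", "B3"),
    ("B1", "C1"),
    ("B1", "C2"),
    ("B1", "C3"),
    ("B3", "C4"),
    ("C3", "D1"),
}


@pytest.fixture
def example_dataset(example_root, example_reposts) -> Dataset:
    users = [User(user_id=u) for u in ["userA"] + [r.repost_id for r in example_reposts]]
    ds = Dataset(posts=[example_root], users=users, reposts=example_reposts)
    ds.flag_missing_users()
    return ds


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with ground truth, shared across tests."""
    cfg = SimConfig(seed=7, n_users=300, n_posts=80)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
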
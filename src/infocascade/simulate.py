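"""Synthetic microblog misinformation data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without platform access:

* five user archetypes (general, platform, inactive, influential,
  mingler) with well-separated authority profiles; counts are lognormal
  (heavy-tailed follower counts), levels truncated discrete normals;
* repost cascades as level-dependent Poisson branching processes in three
  structural regimes — *radiation* (wide first level, little onward
  spread), *sector* and *viral* (a planted level-1 hub whose fan makes a
  deeper level the widest; hub engagement forwards-heavy for sector,
  likes-heavy for viral);
* raw ``//`` chain texts built so the chain parser recovers the true tree
  exactly; timestamps accumulate exponential waits at minute resolution;
* a planted positive link between the root author's follower count and
  the first-level branching rate, so scale rank-correlates with
  followers;
* overdispersed (negative-binomial) engagement counts with likes >>
  forwards on average, and archetype-dependent topic propensities.

Everything is driven by one integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .models import ARCHETYPES, TOPICS, Dataset, Post, RepostRecord, User

REGIMES = ("radiation", "sector", "viral")


def _default_centroids() -> dict:
    # feature -> (mean, sd); posts/followers/following on natural-log scale
    return {
        "general": {
            "urank": (30, 5), "mrank": (1.0, 0.7),
            "posts_count": (7.0, 0.5), "followers_count": (6.5, 0.5),
            "following_count": (6.0, 0.5),
        },
        "platform": {
            "urank": (30, 5), "mrank": (6.0, 0.7),
            "posts_count": (7.0, 0.5), "followers_count": (6.5, 0.5),
            "following_count": (6.0, 0.5),
        },
        "inactive": {
            "urank": (8, 4), "mrank": (0.3, 0.4),
            "posts_count": (2.0, 0.5), "followers_count": (3.0, 0.5),
            "following_count": (4.0, 0.5),
        },
        "influential": {
            "urank": (45, 2), "mrank": (6.5, 0.5),
            "posts_count": (11.0, 0.5), "followers_count": (13.0, 0.5),
            "following_count": (7.0, 0.5),
        },
        "mingler": {
            "urank": (25, 5), "mrank": (2.0, 0.7),
            "posts_count": (4.0, 0.5), "followers_count": (12.0, 0.5),
            "following_count": (7.0, 0.5),
        },
    }


def _default_branching() -> dict:
    return {
        "radiation": [5.0, 0.1, 0.05],
        "sector": [2.0, 0.5, 0.3, 0.1],
        "viral": [2.0, 0.5, 0.3, 0.1],
    }


class SimConfig(BaseModel):
    """Study conditions for the generator; the seed fully determines output."""

    seed: int = 42
    n_users: int = 2500
    #: population shares of the five archetypes (order of ARCHETYPES)
    archetype_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "general": 0.207, "platform": 0.264, "inactive": 0.500,
            "influential": 0.009, "mingler": 0.020,
        }
    )
    archetype_centroids: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=_default_centroids
    )
    n_posts: int = 1000
    #: corpus topic shares (medical misinformation dominates)
    topic_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "government_response": 0.0892, "epidemic_spread": 0.0558,
            "medical_information": 0.4680, "social_livelihood": 0.3609,
            "international_issues": 0.0261,
        }
    )
    regime_mix: dict[str, float] = Field(
        default_factory=lambda: {"radiation": 0.97, "sector": 0.01, "viral": 0.02}
    )
    #: per-regime offspring means lambda_1..lambda_Lmax (0 beyond the list)
    branching: dict[str, list[float]] = Field(default_factory=_default_branching)
    #: extra offspring (Poisson mean) of the planted sector/viral hub,
    #: on top of the count that guarantees the fan out-widens level 1
    hub_extra_offspring: float = 3.0
    #: engagement boost of the hub's dominant metric
    hub_engagement_boost: int = 50
    #: negative-binomial means (dispersion ``nb_dispersion``)
    post_likes_mean: float = 189.0
    post_comments_mean: float = 13.0
    repost_likes_mean: float = 2.0
    nb_dispersion: float = 0.7
    #: exponential inter-repost waiting-time mean, hours
    wait_mean_hours: float = 0.5
    #: exponent linking first-level rate to the author's log follower count
    followers_coupling: float = 1.5
    max_nodes: int = 100_000
    start: dt.datetime = dt.datetime(2019, 12, 1)
    end: dt.datetime = dt.datetime(2021, 2, 1)

    @model_validator(mode="after")
    def _check(self):
        for name, mix in (("archetype_mix", self.archetype_mix),
                          ("topic_mix", self.topic_mix),
                          ("regime_mix", self.regime_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if any(l < 0 for lam in self.branching.values() for l in lam):
            raise ValueError("branching rates must be >= 0")
        return self

    def topic_propensities(self, archetype: str) -> dict[str, float]:
        """Per-archetype topic distribution: inactive users tilt toward
        social/livelihood misinformation, influential users toward medical."""
        w = dict(self.topic_mix)
        if archetype == "inactive":
            w["social_livelihood"] *= 2.0
        elif archetype == "influential":
            w["medical_information"] *= 2.0
            w["social_livelihood"] *= 0.5
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}


@dataclass
class CascadeTruth:
    """Ground truth for one generated cascade."""

    root_post_id: str
    regime: str
    edges: list[tuple[str, str]] = field(default_factory=list)
    levels: dict[str, int] = field(default_factory=dict)
    hub: Optional[str] = None
    truncated: bool = False


@dataclass
class SimTruth:
    archetypes: pd.DataFrame  # user_id, archetype
    regimes: pd.DataFrame  # post_id, regime, truncated
    cascades: list[CascadeTruth] = field(default_factory=list)


def _nb(rng: np.random.Generator, mean: float, disp: float, size=None):
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=size)


def _trunc_int(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


_VERIFIED_P = {
    "general": 0.4, "platform": 0.5, "inactive": 0.15,
    "influential": 0.95, "mingler": 0.5,
}
_VTYPE = ("personal", "government", "media", "business")


def simulate_users(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[list[User], pd.DataFrame]:
    """Draw users per archetype; returns (users, truth labels)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mix = np.array([cfg.archetype_mix[a] for a in ARCHETYPES])
    labels = rng.choice(len(ARCHETYPES), size=cfg.n_users, p=mix)
    users: list[User] = []
    rows = []
    for i, lab in enumerate(labels):
        arch = ARCHETYPES[lab]
        cen = cfg.archetype_centroids[arch]
        verified = bool(rng.random() < _VERIFIED_P[arch])
        users.append(
            User(
                user_id=f"u{i:05d}",
                verified=verified,
                verification_type=str(rng.choice(_VTYPE)) if verified else "none",
                urank=_trunc_int(rng, *cen["urank"], 0, 48),
                mrank=_trunc_int(rng, *cen["mrank"], 0, 7),
                posts_count=int(round(math.exp(rng.normal(*cen["posts_count"])))),
                followers_count=int(round(math.exp(rng.normal(*cen["followers_count"])))),
                following_count=int(round(math.exp(rng.normal(*cen["following_count"])))),
            )
        )
        rows.append({"user_id": f"u{i:05d}", "archetype": arch})
    return users, pd.DataFrame(rows)


def _floor_minute(ts: dt.datetime) -> dt.datetime:
    return ts.replace(second=0, microsecond=0)


def simulate_cascade(
    cfg: SimConfig,
    regime: str,
    root_post_id: str,
    root_ts: dt.datetime,
    reposter_pool: list[str],
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> tuple[list[RepostRecord], CascadeTruth]:
    """One branching-process cascade with parser-recoverable chain texts.

    Each level-k node spawns Poisson(lambda_k) children; in the sector and
    viral regimes one level-1 node is the planted hub, whose offspring
    count always exceeds the first-level width (the fan) and whose
    engagement is forwards-heavy (sector) or likes-heavy (viral).
    Reposters within one cascade are distinct, so parent resolution from
    the chain texts is exact.
    """
    if regime not in cfg.branching:
        raise ValueError(f"unknown regime {regime!r}")
    lambdas = cfg.branching[regime]
    truth = CascadeTruth(root_post_id=root_post_id, regime=regime)
    cap = min(cfg.max_nodes, len(reposter_pool))

    lam1 = (lambdas[0] if lambdas else 0.0) * rate_scale
    k1 = int(rng.poisson(lam1))
    if regime in ("sector", "viral"):
        k1 = max(k1, 1)  # the hub must exist
    k1 = min(k1, cap)
    if k1 == 0:
        return [], truth

    pool = list(rng.choice(reposter_pool, size=cap, replace=False))
    pool_iter = iter(pool)

    records: list[RepostRecord] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"{root_post_id}r{counter:04d}"

    # node bookkeeping: id -> (reposter, chain_text, timestamp, children)
    meta: dict[str, dict] = {}

    def spawn(parent_id, parent_meta, level) -> Optional[str]:
        try:
            reposter = next(pool_iter)
        except StopIteration:
            truth.truncated = True
            return None
        rid = new_id()
        wait = rng.exponential(cfg.wait_mean_hours)
        ts = _floor_minute(parent_meta["ts"] + dt.timedelta(hours=wait))
        comment = "" if rng.random() < 0.2 else f"fw{counter}"
        if level == 1:
            chain = comment
        else:
            chain = f"{comment}//@{parent_meta['reposter']}: {parent_meta['chain']}"
        meta[rid] = {"reposter": reposter, "chain": chain, "ts": ts, "children": 0}
        truth.edges.append((parent_id, rid))
        truth.levels[rid] = level
        if parent_id != root_post_id:
            parent_meta["children"] += 1
        return rid

    root_meta = {"reposter": "", "chain": "", "ts": root_ts, "children": 0}
    frontier = []
    for _ in range(k1):
        rid = spawn(root_post_id, root_meta, 1)
        if rid:
            frontier.append(rid)

    if regime in ("sector", "viral") and frontier:
        truth.hub = frontier[0]

    level = 1
    while frontier and len(meta) < cap:
        next_frontier = []
        lam = lambdas[level] if level < len(lambdas) else 0.0
        for node in frontier:
            if node == truth.hub and level == 1:
                # the fan: always out-widens the first level
                n_children = len(frontier) + 1 + int(rng.poisson(cfg.hub_extra_offspring))
            else:
                n_children = int(rng.poisson(lam))
            for _ in range(n_children):
                if len(meta) >= cap:
                    truth.truncated = True
                    break
                rid = spawn(node, meta[node], level + 1)
                if rid:
                    next_frontier.append(rid)
        frontier = next_frontier
        level += 1

    for rid, m in meta.items():
        forwards = m["children"]
        likes = int(_nb(rng, cfg.repost_likes_mean, cfg.nb_dispersion))
        if rid == truth.hub:
            if regime == "sector":
                forwards += cfg.hub_engagement_boost
                likes = min(likes, forwards - 1) if forwards > 0 else 0
            else:  # viral
                likes = 2 * forwards + cfg.hub_engagement_boost
        records.append(
            RepostRecord(
                repost_id=rid,
                root_post_id=root_post_id,
                reposter_id=m["reposter"],
                timestamp=m["ts"],
                chain_text=m["chain"],
                forwards=int(forwards),
                likes=int(likes),
            )
        )
    return records, truth


_SENTIMENT_BETA = {
    "government_response": (3, 3),
    "epidemic_spread": (2, 5),  # epidemic-spread misinformation skews negative
    "medical_information": (5, 2),  # unproven cures skew positive
    "social_livelihood": (3, 3),
    "international_issues": (3, 3),
}


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Full synthetic dataset plus ground-truth tables.

    Truth tables (archetypes, regimes, true edges) are kept separate from
    the Dataset so pipeline code cannot accidentally peek at them.
    """
    rng = np.random.default_rng(cfg.seed)
    users, arch_truth = simulate_users(cfg, rng)
    arch_by_user = dict(zip(arch_truth["user_id"], arch_truth["archetype"]))
    user_ids = [u.user_id for u in users]
    followers = {u.user_id: u.followers_count for u in users}
    mean_logf = float(np.mean([math.log1p(f) for f in followers.values()]))

    topics = list(cfg.topic_mix)
    regimes = list(cfg.regime_mix)
    regime_p = np.array([cfg.regime_mix[r] for r in regimes])
    window_min = int((cfg.end - cfg.start).total_seconds() // 60)

    posts: list[Post] = []
    reposts: list[RepostRecord] = []
    truth = SimTruth(
        archetypes=arch_truth,
        regimes=pd.DataFrame(columns=["post_id", "regime", "truncated"]),
    )
    regime_rows = []
    for j in range(cfg.n_posts):
        pid = f"p{j:05d}"
        author = user_ids[int(rng.integers(len(user_ids)))]
        arch = arch_by_user[author]
        props = cfg.topic_propensities(arch)
        topic = str(rng.choice(topics, p=[props[t] for t in topics]))
        ts = cfg.start + dt.timedelta(minutes=int(rng.integers(window_min)))
        regime = str(rng.choice(regimes, p=regime_p))
        # planted scale-followers link: first-level rate grows with the
        # author's log follower count
        rate_scale = float(
            np.clip((math.log1p(followers[author]) / mean_logf) ** cfg.followers_coupling, 0.05, 8.0)
        )
        pool = [u for u in user_ids if u != author]
        recs, ctruth = simulate_cascade(cfg, regime, pid, ts, pool, rng, rate_scale)
        reposts.extend(recs)
        a, b = _SENTIMENT_BETA[topic]
        posts.append(
            Post(
                post_id=pid,
                author_id=author,
                timestamp=ts,
                text=f"claim {j} about {topic}",
                topic=topic,
                forwards=len(recs),
                comments=int(_nb(rng, cfg.post_comments_mean, cfg.nb_dispersion)),
                likes=int(_nb(rng, cfg.post_likes_mean, cfg.nb_dispersion)),
                sentiment=float(rng.beta(a, b)),
            )
        )
        regime_rows.append(
            {"post_id": pid, "regime": regime, "truncated": ctruth.truncated}
        )
        truth.cascades.append(ctruth)

    truth.regimes = pd.DataFrame(regime_rows)
    ds = Dataset(posts=posts, users=users, reposts=reposts)
    ds.flag_missing_users()
    return ds, truth


def write_truth(truth: SimTruth, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.archetypes.to_csv(out / "truth_archetypes.csv", index=False)
    truth.regimes.to_csv(out / "truth_regimes.csv", index=False)
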
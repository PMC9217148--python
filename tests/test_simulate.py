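"""Properties of the synthetic-data generator."""

import datetime as dt
import filecmp
import math

import numpy as np
import pytest

from infocascade import chains, io, trees
from infocascade.models import ARCHETYPES, Post
from infocascade.simulate import (
    SimConfig,
    simulate_cascade,
    simulate_dataset,
    simulate_users,
)

T0 = dt.datetime(2020, 3, 1, 10, 0)


def test_fixed_seed_means_byte_identical_files(tmp_path):
    cfg = SimConfig(seed=9, n_users=80, n_posts=25)
    for sub in ("a", "b"):
        ds, _ = simulate_dataset(cfg)
        io.write_dataset(ds, tmp_path / sub, fmt="csv")
    for table in ("posts", "users", "reposts"):
        assert filecmp.cmp(
            tmp_path / "a" / f"{table}.csv", tmp_path / "b" / f"{table}.csv",
            shallow=False,
        )


def test_single_archetype_mix():
    mix = {a: 0.0 for a in ARCHETYPES}
    mix["inactive"] = 1.0
    cfg = SimConfig(seed=1, n_users=50, archetype_mix=mix)
    _, truth = simulate_users(cfg)
    assert (truth["archetype"] == "inactive").all()


def test_archetype_mix_within_sampling_error():
    cfg = SimConfig(seed=2, n_users=5000)
    _, truth = simulate_users(cfg)
    shares = truth["archetype"].value_counts(normalize=True)
    for arch, p in cfg.archetype_mix.items():
        se = math.sqrt(p * (1 - p) / cfg.n_users)
        assert abs(shares.get(arch, 0.0) - p) <= 3 * se + 1e-9


def test_user_feature_ranges():
    cfg = SimConfig(seed=3, n_users=400)
    users, _ = simulate_users(cfg)
    for u in users:
        assert 0 <= u.urank <= 48 and 0 <= u.mrank <= 7
        assert min(u.posts_count, u.followers_count, u.following_count) >= 0


def test_zero_rates_give_empty_cascade():
    cfg = SimConfig(branching={"radiation": [0.0]})
    rng = np.random.default_rng(0)
    recs, truth = simulate_cascade(
        cfg, "radiation", "p0", T0, [f"u{i}" for i in range(50)], rng
    )
    assert recs == [] and truth.edges == []


def test_level1_offspring_mean_matches_rate():
    """Mean first-level width over many cascades ~ lambda_1 (Poisson MLE)."""
    cfg = SimConfig(branching={"radiation": [4.0, 0.1]})
    rng = np.random.default_rng(6)
    pool = [f"u{i}" for i in range(2000)]
    widths = []
    for j in range(600):
        _, truth = simulate_cascade(cfg, "radiation", f"p{j}", T0, pool, rng)
        widths.append(sum(1 for lvl in truth.levels.values() if lvl == 1))
    se = math.sqrt(4.0 / len(widths))
    assert abs(np.mean(widths) - 4.0) <= 3 * se


def test_branching_expectation_two_level():
    """E[scale] = lambda_1 + lambda_1*lambda_2 for a two-level process."""
    lam1, lam2 = 3.0, 0.8
    cfg = SimConfig(branching={"radiation": [lam1, lam2]})
    rng = np.random.default_rng(8)
    pool = [f"u{i}" for i in range(5000)]
    scales = []
    for j in range(500):
        _, truth = simulate_cascade(cfg, "radiation", f"p{j}", T0, pool, rng)
        scales.append(len(truth.levels))
    expected = lam1 + lam1 * lam2
    se = np.std(scales, ddof=1) / math.sqrt(len(scales))
    assert abs(np.mean(scales) - expected) <= 3.5 * se


def test_hub_regimes_have_planted_structure_and_engagement():
    cfg = SimConfig()
    rng = np.random.default_rng(10)
    pool = [f"u{i}" for i in range(3000)]
    for regime, heavier in (("sector", "forwards"), ("viral", "likes")):
        recs, truth = simulate_cascade(cfg, regime, "p0", T0, pool, rng)
        assert truth.hub is not None
        hub = next(r for r in recs if r.repost_id == truth.hub)
        if heavier == "forwards":
            assert hub.forwards > hub.likes
        else:
            assert hub.likes > hub.forwards
        widths = {}
        for lvl in truth.levels.values():
            widths[lvl] = widths.get(lvl, 0) + 1
        assert max(w for lvl, w in widths.items() if lvl > 1) > widths[1]


def test_generated_chains_reparse_to_true_edges(small_sim):
    """Parser output equals the generator's true edge list for every cascade."""
    _, ds, truth = small_sim
    by_root = ds.reposts_by_root()
    for ct in truth.cascades:
        recs = by_root.get(ct.root_post_id, [])
        res = chains.resolve_parents(recs, root_post_id=ct.root_post_id)
        assert res.orphans == []
        assert sorted(res.edges) == sorted(ct.edges)


def test_metrics_agree_between_true_tree_and_parsed_chains(small_sim):
    """Metrics computed from parsed chains equal metrics from truth edges."""
    _, ds, truth = small_sim
    posts = ds.post_index()
    by_root = ds.reposts_by_root()
    for ct in truth.cascades:
        recs = by_root.get(ct.root_post_id, [])
        res = chains.resolve_parents(recs, root_post_id=ct.root_post_id)
        t_parsed = trees.build_tree(posts[ct.root_post_id], res.edges, res.parsed)
        t_true = trees.build_tree(posts[ct.root_post_id], ct.edges, res.parsed)
        m1, m2 = trees.compute_metrics(t_parsed), trees.compute_metrics(t_true)
        assert (m1.scale, m1.depth, m1.max_width, m1.avg_width, m1.speed) == (
            m2.scale, m2.depth, m2.max_width, m2.avg_width, m2.speed,
        )


def test_planted_scale_followers_correlation(small_sim):
    """The follower-to-branching coupling plants a positive rank link
    between cascade scale and the root author's follower count."""
    from infocascade import stats

    _, ds, truth = small_sim
    posts = ds.posts_df()
    users = ds.users_df()
    joined = posts.merge(users, left_on="author_id", right_on="user_id")
    res = stats.spearman(joined["forwards"], joined["followers_count"])
    assert res.rho > 0


def test_topic_propensities_respected():
    cfg = SimConfig(seed=12, n_users=400, n_posts=600)
    ds, truth = simulate_dataset(cfg)
    posts = ds.posts_df().merge(
        truth.archetypes, left_on="author_id", right_on="user_id"
    )
    sub = posts[posts["archetype"] == "inactive"]
    p = cfg.topic_propensities("inactive")["social_livelihood"]
    share = (sub["topic"] == "social_livelihood").mean()
    se = math.sqrt(p * (1 - p) / len(sub))
    assert abs(share - p) <= 3 * se + 0.02


def test_invalid_regime_and_mix_validation():
    with pytest.raises(ValueError):
        SimConfig(topic_mix={"medical_information": 0.5})
    cfg = SimConfig()
    with pytest.raises(ValueError, match="regime"):
        simulate_cascade(
            cfg, "spiral", "p0", T0, ["u1"], np.random.default_rng(0)
        )
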
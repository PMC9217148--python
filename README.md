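# infocascade

Reconstruction and analysis of misinformation repost cascades on
microblog platforms.

During a public-health crisis, health misinformation spreads through
repost (forward) cascades: an original post is forwarded, the forwards
are forwarded, and the platform records each repost's full forwarding
history as a `//`-delimited chain embedded in its text. `infocascade` is
a pipeline for infodemiology researchers who have such raw post / user /
repost tables and want to quantify *how* each false claim spread and
*who* spread it:

1. **Chain parsing** — each repost's forwarding level is the number of
   `//`-separated segments of its text (root = level 0, a direct repost
   = level 1), and its parent is the level-(k−1) repost whose author
   matches the leading `@handle:` mention of the second segment.
2. **Cascade metrics** — for the dissemination tree of each root post:
   scale *S* (number of repost nodes), depth *D* (maximum level),
   maximum width *W*<sub>max</sub> = max<sub>ℓ≥1</sub> *n*<sub>ℓ</sub>
   (nodes at the widest repost level), average width
   *W̄* = *S*/*D*, and speed *S*/Δt in reposts per hour over the
   cascade's lifetime.
3. **Structural typology** — *radiation* (the first level is at least as
   wide as every deeper level), *sector* / *viral* (a deeper level is
   wider; split by whether the most-engaged repost node attracts more
   forwards or more likes).
4. **User clustering** — k-means on five authority features (user
   level, membership level, posts / followers / following counts;
   counts log1p-transformed, all z-scored), elbow-selected k, and
   archetype naming at k = 5 (general, platform, inactive, influential,
   mingler).
5. **Association statistics** — Spearman rank correlations between
   cascade topology and creator authority, per-topic summaries with
   t-based 95% CIs, weekly topic/sentiment aggregates, and
   Krippendorff's alpha for topic-coding reliability.
6. **Synthetic data** — a seeded branching-process generator that
   emulates all of the above with ground truth, so the pipeline is fully
   testable without platform access.

## Worked example

A root post A forwarded by B1, B2 and B3; B1 forwarded by C1, C2 and C3;
B3 by C4; and C3 by D1 — expressed only through the raw chain texts
(e.g. D1's text is `"d1//@C3: c3//@B1: b1"`):

```python
import datetime as dt
from infocascade import chains, trees, typology
from infocascade.models import Post, RepostRecord

t0 = dt.datetime(2020, 3, 1, 10, 0)
root = Post(post_id="A", author_id="newsdesk", timestamp=t0)

def rec(rid, minutes, chain, forwards=0):
    return RepostRecord(repost_id=rid, root_post_id="A", reposter_id=rid,
                        timestamp=t0 + dt.timedelta(minutes=minutes),
                        chain_text=chain, forwards=forwards)

reposts = [
    rec("B1", 10, "b1", forwards=3), rec("B2", 12, "b2"),
    rec("B3", 15, "b3", forwards=1),
    rec("C1", 30, "c1//@B1: b1"), rec("C2", 32, "c2//@B1: b1"),
    rec("C3", 35, "c3//@B1: b1", forwards=1),
    rec("C4", 40, "c4//@B3: b3"),
    rec("D1", 50, "d1//@C3: c3//@B1: b1"),
]

res = chains.resolve_parents(reposts, root_post_id="A")
tree = trees.build_tree(root, res.edges, res.parsed)
m = trees.compute_metrics(tree)
d = typology.classify_network(tree)
print(f"scale={m.scale} depth={m.depth} max_width={m.max_width} "
      f"avg_width={m.avg_width:.3f} speed={m.speed:.2f} type={d.net_type}")
```

prints

```
scale=8 depth=3 max_width=4 avg_width=2.667 speed=9.60 type=sector
```

Eight reposts (scale 8) spread over three levels (depth 3); the second
level, with four nodes, is the widest, so the cascade is not radiation,
and the busiest repost (B1, 3 forwards, 0 likes) makes it sector. The
last repost arrives 50 minutes after the root: 8 / (50/60 h) = 9.6
reposts per hour.

## Command line

```sh
infocascade simulate --seed 7 --n-users 300 --n-posts 100 --out data/
infocascade all --in data/ --out results/ --k 5
```

runs the whole pipeline (parse → trees → metrics → typology →
clustering → associations) and writes `cascade_metrics.csv`,
`clusters.csv`, `correlations.csv`, `group_summary.csv`, `timebins.csv`
and a `report.md` whose tables include, for the simulated corpus above:

```
## Network types

| category | n | share |
|---|---|---|
| radiation | 95 | 97.94% |
| sector | 2 | 2.06% |
```

Stage subcommands (`parse`, `cascade`, `classify`, `cluster`,
`associate`, `report`) run individual steps; `--help` lists options.

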
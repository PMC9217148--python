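"""Dissemination trees and their scale, depth, width and speed metrics.

A dissemination tree is rooted at the original post (level 0); every other
node is a repost at level = its distance from the root. The metrics follow
the standard cascade conventions:

* **scale** — number of repost nodes (root excluded); equals the number of
  forwards the original post received.
* **depth** — maximum forwarding level reached.
* **max_width** — largest number of nodes at any repost level.
* **avg_width** — mean node count over levels 1..depth, i.e. scale/depth,
  so ``avg_width * depth == scale`` exactly.
* **speed** — reposts per hour over the cascade lifetime (root timestamp to
  latest repost), with elapsed time floored at one minute; undefined for a
  cascade with no reposts.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .chains import ParsedRepost
from .models import Post

#: elapsed-time floor for the speed metric (timestamps have minute resolution)
MIN_ELAPSED_HOURS = 1.0 / 60.0


class TreeStructureError(ValueError):
    """The supplied edges do not form a forest (cycle or multi-parent node)."""


@dataclass
class DisseminationTree:
    """Rooted tree of one post and all reposts reachable from it."""

    root: str
    graph: nx.DiGraph  # nodes carry level, timestamp, forwards, likes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def level_widths(self) -> dict[int, int]:
        """Node count per repost level (levels >= 1)."""
        counts = Counter(
            lvl for _, lvl in self.graph.nodes(data="level") if lvl >= 1
        )
        return dict(sorted(counts.items()))

    def repost_nodes(self) -> list[str]:
        return [n for n, lvl in self.graph.nodes(data="level") if lvl >= 1]


@dataclass
class CascadeMetrics:
    root: str
    scale: int
    depth: int
    max_width: int
    avg_width: float
    speed: Optional[float]
    net_type: Optional[str] = None


def build_tree(
    root: Post,
    edges: list[tuple[str, str]],
    parsed: list[ParsedRepost],
) -> DisseminationTree:
    """Assemble the tree for ``root`` from resolved parent->child edges.

    Only records reachable from the root are included; disconnected edges
    (e.g. reposts of a different root that slipped in) are excluded.
    """
    g = nx.DiGraph()
    info = {p.repost_id: p for p in parsed}
    g.add_node(
        root.post_id,
        level=0,
        timestamp=root.timestamp,
        forwards=root.forwards,
        likes=root.likes,
    )
    for parent, child in edges:
        g.add_edge(parent, child)

    multi = [n for n in g.nodes if g.in_degree(n) > 1]
    if multi:
        raise TreeStructureError(f"node(s) with multiple parents: {multi}")
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise TreeStructureError(f"cycle detected: {cycle}")

    reachable = {root.post_id} | nx.descendants(g, root.post_id)
    tree = g.subgraph(reachable).copy()
    for node in tree.nodes:
        if node == root.post_id:
            continue
        p = info.get(node)
        lvl = nx.shortest_path_length(tree, root.post_id, node)
        tree.nodes[node].update(
            level=lvl,
            timestamp=p.timestamp if p else None,
            forwards=p.forwards if p else 0,
            likes=p.likes if p else 0,
        )
        if p is not None and p.level != lvl:
            raise TreeStructureError(
                f"repost {node}: chain level {p.level} != tree distance {lvl}"
            )
    return DisseminationTree(root=root.post_id, graph=tree)


def compute_metrics(t: DisseminationTree) -> CascadeMetrics:
    """Scale, depth, maximum/average width and speed of one tree."""
    widths = t.level_widths()
    scale = sum(widths.values())
    if scale == 0:
        return CascadeMetrics(t.root, 0, 0, 0, 0.0, None)
    depth = max(widths)
    max_width = max(widths.values())
    avg_width = scale / depth
    speed = _speed(t, scale)
    return CascadeMetrics(t.root, scale, depth, max_width, avg_width, speed)


def _speed(t: DisseminationTree, scale: int) -> Optional[float]:
    root_ts: dt.datetime = t.graph.nodes[t.root]["timestamp"]
    repost_ts = [
        ts
        for n, ts in t.graph.nodes(data="timestamp")
        if n != t.root and ts is not None
    ]
    if root_ts is None or not repost_ts:
        return None
    elapsed_h = (max(repost_ts) - root_ts).total_seconds() / 3600.0
    return scale / max(elapsed_h, MIN_ELAPSED_HOURS)


def metrics_table(metrics: list[CascadeMetrics]):
    """Cascade metrics as a DataFrame (one row per root post)."""
    import pandas as pd

    rows = [
        {
            "post_id": m.root,
            "scale": m.scale,
            "depth": m.depth,
            "max_width": m.max_width,
            "avg_width": m.avg_width,
            "speed": math.nan if m.speed is None else m.speed,
            "net_type": m.net_type,
        }
        for m in metrics
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "post_id",
            "scale",
            "depth",
            "max_width",
            "avg_width",
            "speed",
            "net_type",
        ],
    )
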
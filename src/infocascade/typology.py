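"""Structural classification of dissemination trees.

Three patterns are distinguished:

* **radiation** — the first forwarding level is at least as wide as every
  deeper level: a star-dominated broadcast from the original poster.
  Ties count as radiation, so every depth-1 cascade is radiation.
* **sector** — some deeper level is strictly wider than level 1 and the
  most-engaged repost node attracts at least as many forwards as likes
  (a secondary hub that actively re-broadcasts).
* **viral** — as sector, but the most-engaged repost node attracts more
  likes than forwards (engagement without onward spread).

A cascade with no reposts is **undisseminated**. The most-engaged repost
node (the *pivot*) is the one maximizing max(forwards, likes), ties broken
by larger forwards, then earlier timestamp, then node id.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

from .trees import DisseminationTree

RADIATION = "radiation"
SECTOR = "sector"
VIRAL = "viral"
UNDISSEMINATED = "undisseminated"

NET_TYPES = (RADIATION, SECTOR, VIRAL, UNDISSEMINATED)

_FAR_FUTURE = dt.datetime.max


@dataclass
class NetTypeDecision:
    net_type: str
    level1_width: int
    max_other_width: int
    pivot_node: Optional[str] = None
    pivot_forwards: Optional[int] = None
    pivot_likes: Optional[int] = None


def classify_network(t: DisseminationTree) -> NetTypeDecision:
    """Label one tree as radiation, sector, viral or undisseminated."""
    widths = t.level_widths()
    if not widths:
        return NetTypeDecision(UNDISSEMINATED, 0, 0)
    level1 = widths.get(1, 0)
    max_other = max((w for lvl, w in widths.items() if lvl > 1), default=0)
    if level1 >= max_other:
        return NetTypeDecision(RADIATION, level1, max_other)

    pivot = _pivot_node(t)
    f = t.graph.nodes[pivot]["forwards"]
    l = t.graph.nodes[pivot]["likes"]
    net_type = SECTOR if f >= l else VIRAL
    return NetTypeDecision(net_type, level1, max_other, pivot, f, l)


def _pivot_node(t: DisseminationTree) -> str:
    def key(node: str):
        d = t.graph.nodes[node]
        ts = d.get("timestamp") or _FAR_FUTURE
        return (-max(d["forwards"], d["likes"]), -d["forwards"], ts, node)

    return min(t.repost_nodes(), key=key)
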
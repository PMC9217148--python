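"""Forwarding-level extraction and parent resolution from "//" chain texts.

On the platform, a repost's text embeds the texts of the reposts it was
forwarded from, newest first, separated by ``//``; each inherited segment
opens with an ``@handle:`` mention of its author. The number of segments
therefore equals the forwarding level (root post = level 0, a direct
repost = level 1), and the leading mention of the *second* segment names
the parent reposter.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .models import RepostRecord

log = logging.getLogger(__name__)

SEPARATOR = "//"

_MENTION = re.compile(r"^\s*@([^:\s]+)\s*:")


@dataclass
class ParsedRepost:
    """A repost with its forwarding level and (eventually) resolved parent."""

    repost_id: str
    root_post_id: str
    reposter_id: str
    timestamp: dt.datetime
    chain_segments: list[str]
    forwards: int = 0
    likes: int = 0
    resolved_parent: Optional[str] = None

    @property
    def level(self) -> int:
        return len(self.chain_segments)


@dataclass
class Orphan:
    repost_id: str
    level: int
    reason: str


@dataclass
class ResolutionResult:
    """Edges + orphans conserve the input: len(edges) + len(orphans) == n."""

    root_post_id: str
    edges: list[tuple[str, str]] = field(default_factory=list)
    parsed: list[ParsedRepost] = field(default_factory=list)
    orphans: list[Orphan] = field(default_factory=list)


def extract_level(chain_text: str, separator: str = SEPARATOR) -> int:
    """Forwarding level of a repost = number of separator-delimited segments.

    An empty text is a bare forward and counts as one segment (level 1);
    empty segments between separators are bare forwards along the chain and
    count as well.
    """
    return len(chain_text.split(separator))


def parse_segments(chain_text: str, separator: str = SEPARATOR) -> list[str]:
    """Split a chain text into its segments, newest first."""
    return chain_text.split(separator)


def leading_handle(segment: str) -> Optional[str]:
    """The ``@name:`` mention opening a segment, or None.

    Matching is case-sensitive and exact, per platform convention.
    """
    m = _MENTION.match(segment)
    return m.group(1) if m else None


def parse_repost(record: RepostRecord, separator: str = SEPARATOR) -> ParsedRepost:
    return ParsedRepost(
        repost_id=record.repost_id,
        root_post_id=record.root_post_id,
        reposter_id=record.reposter_id,
        timestamp=record.timestamp,
        chain_segments=parse_segments(record.chain_text, separator),
        forwards=record.forwards,
        likes=record.likes,
    )


def _pick_parent(
    candidates: list[ParsedRepost], child: ParsedRepost
) -> ParsedRepost:
    """Deterministic choice among same-handle same-level candidates.

    Prefer the nearest earlier-or-equal timestamp; if none precedes the
    child, the earliest candidate; final ties break on repost_id.
    """
    earlier = sorted(
        (c for c in candidates if c.timestamp <= child.timestamp),
        key=lambda c: c.repost_id,
    )
    if earlier:
        # max() keeps the first maximal element, i.e. smallest repost_id on ties
        return max(earlier, key=lambda c: c.timestamp)
    return min(candidates, key=lambda c: (c.timestamp, c.repost_id))


def resolve_parents(
    reposts: list[RepostRecord] | list[ParsedRepost],
    root_post_id: str | None = None,
    separator: str = SEPARATOR,
) -> ResolutionResult:
    """Resolve the parent of every repost of one root post.

    Level-1 reposts attach to the root. A level-k repost (k > 1) attaches
    to the level-(k-1) repost whose reposter handle matches the leading
    mention of its second chain segment. Records whose parent cannot be
    found (e.g. the intermediate repost was deleted) are dropped as orphans
    and counted; they are never re-attached to the root, which would
    deflate depth and inflate first-level width.
    """
    parsed = [
        r if isinstance(r, ParsedRepost) else parse_repost(r, separator)
        for r in reposts
    ]
    if root_post_id is None:
        roots = {p.root_post_id for p in parsed}
        if len(roots) > 1:
            raise ValueError(f"reposts span multiple roots: {sorted(roots)}")
        root_post_id = roots.pop() if roots else ""
    else:
        foreign = [p.repost_id for p in parsed if p.root_post_id != root_post_id]
        if foreign:
            raise ValueError(f"reposts of a different root: {foreign}")

    result = ResolutionResult(root_post_id=root_post_id)
    by_level_handle: dict[tuple[int, str], list[ParsedRepost]] = {}
    for p in parsed:
        by_level_handle.setdefault((p.level, p.reposter_id), []).append(p)

    for p in sorted(parsed, key=lambda q: (q.level, q.timestamp, q.repost_id)):
        if p.level == 1:
            p.resolved_parent = root_post_id
            result.edges.append((root_post_id, p.repost_id))
            result.parsed.append(p)
            continue
        handle = leading_handle(p.chain_segments[1])
        if handle is None:
            result.orphans.append(
                Orphan(p.repost_id, p.level, "no @handle: mention in second segment")
            )
            continue
        candidates = by_level_handle.get((p.level - 1, handle), [])
        # a parent dropped as an orphan cannot adopt children
        candidates = [c for c in candidates if c.resolved_parent is not None]
        if not candidates:
            result.orphans.append(
                Orphan(
                    p.repost_id,
                    p.level,
                    f"no level-{p.level - 1} repost by @{handle}",
                )
            )
            continue
        parent = _pick_parent(candidates, p)
        p.resolved_parent = parent.repost_id
        result.edges.append((parent.repost_id, p.repost_id))
        result.parsed.append(p)

    if result.orphans:
        log.warning(
            "root %s: dropped %d orphan repost(s)", root_post_id, len(result.orphans)
        )
    return result
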
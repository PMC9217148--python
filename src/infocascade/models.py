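"""Domain types for microblog misinformation-diffusion analysis.

The pipeline consumes three tables: original posts (with topic label and
engagement counts), the users who authored them (with authority features),
and repost records whose free text carries a ``//``-delimited forward chain.
All three are validated row-by-row against the invariants below; a
:class:`Dataset` bundles the validated collections.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

TOPICS = (
    "government_response",
    "epidemic_spread",
    "medical_information",
    "social_livelihood",
    "international_issues",
)

VERIFICATION_TYPES = ("personal", "government", "media", "business", "none")

ARCHETYPES = ("general", "platform", "inactive", "influential", "mingler")

#: Authority features used for clustering, in canonical column order.
AUTHORITY_FEATURES = (
    "urank",
    "mrank",
    "posts_count",
    "followers_count",
    "following_count",
)


class Post(BaseModel):
    """An original message carrying misinformation."""

    post_id: str
    author_id: str
    timestamp: dt.datetime
    text: str = ""
    topic: Optional[str] = None
    forwards: int = Field(ge=0, default=0)
    comments: int = Field(ge=0, default=0)
    likes: int = Field(ge=0, default=0)
    sentiment: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @field_validator("topic")
    @classmethod
    def _topic_known(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in TOPICS:
            raise ValueError(f"unknown topic {v!r}; expected one of {TOPICS}")
        return v


class User(BaseModel):
    """An account with verification, level, membership and interaction counts.

    ``urank`` is the platform user level (0-48, a proxy for activity);
    ``mrank`` the paid membership level (0-7, a proxy for loyalty).
    """

    user_id: str
    verified: bool = False
    verification_type: str = "none"
    mrank: int = Field(ge=0, le=7, default=0)
    urank: int = Field(ge=0, le=48, default=0)
    posts_count: int = Field(ge=0, default=0)
    followers_count: int = Field(ge=0, default=0)
    following_count: int = Field(ge=0, default=0)

    @field_validator("verification_type")
    @classmethod
    def _vtype_known(cls, v: str) -> str:
        if v not in VERIFICATION_TYPES:
            raise ValueError(
                f"unknown verification_type {v!r}; expected one of {VERIFICATION_TYPES}"
            )
        return v


class RepostRecord(BaseModel):
    """One forward of a post, carrying the raw ``//`` chain text."""

    repost_id: str
    root_post_id: str
    reposter_id: str
    timestamp: dt.datetime
    chain_text: str = ""
    forwards: int = Field(ge=0, default=0)
    likes: int = Field(ge=0, default=0)
    parent_repost_id: Optional[str] = None


@dataclass
class Dataset:
    """Validated collections of posts, users and repost records.

    ``missing_users`` lists author/reposter ids referenced by posts or
    reposts but absent from the user table (e.g. blocked accounts); such
    references are flagged, never dropped.
    """

    posts: list[Post] = field(default_factory=list)
    users: list[User] = field(default_factory=list)
    reposts: list[RepostRecord] = field(default_factory=list)
    missing_users: set[str] = field(default_factory=set)

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.posts), len(self.users), len(self.reposts))

    def posts_df(self) -> pd.DataFrame:
        return _to_frame(self.posts, Post)

    def users_df(self) -> pd.DataFrame:
        return _to_frame(self.users, User)

    def reposts_df(self) -> pd.DataFrame:
        return _to_frame(self.reposts, RepostRecord)

    def post_index(self) -> dict[str, Post]:
        return {p.post_id: p for p in self.posts}

    def reposts_by_root(self) -> dict[str, list[RepostRecord]]:
        by_root: dict[str, list[RepostRecord]] = {}
        for r in self.reposts:
            by_root.setdefault(r.root_post_id, []).append(r)
        return by_root

    def flag_missing_users(self) -> set[str]:
        """Record referenced-but-absent user ids; returns the set."""
        known = {u.user_id for u in self.users}
        refs = {p.author_id for p in self.posts} | {
            r.reposter_id for r in self.reposts
        }
        self.missing_users = refs - known
        return self.missing_users


def _to_frame(records: list, model: type[BaseModel]) -> pd.DataFrame:
    cols = list(model.model_fields)
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.model_dump() for r in records], columns=cols)
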
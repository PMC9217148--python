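"""Authority-feature clustering of misinformation posters.

Users are described by five authority features: platform user level
(urank), membership level (mrank), and posts/followers/following counts.
Count features are heavy-tailed (follower counts average in the hundreds
of thousands), so they are log1p-transformed before z-scoring; without
this, raw follower counts would dominate Euclidean distance entirely.

k is chosen by the elbow method, formalized as the k maximizing the second
difference of total within-cluster sum of squares; mean silhouette is
reported alongside. With k = 5 the clusters are named by centroid profile
as the five archetypes commonly found among such posters: general,
platform, inactive, influential users, and minglers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .models import ARCHETYPES, AUTHORITY_FEATURES

log = logging.getLogger(__name__)

#: heavy-tailed count features, log1p-transformed before z-scoring
COUNT_FEATURES = ("posts_count", "followers_count", "following_count")


def authority_features(users_df: pd.DataFrame) -> pd.DataFrame:
    """One row per user, the five authority features, user_id as index."""
    feats = users_df.set_index("user_id")[list(AUTHORITY_FEATURES)].astype(float)
    complete = feats.dropna()
    if len(complete) < len(feats):
        log.warning("dropped %d users with missing features", len(feats) - len(complete))
    return complete


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature z-scores; count features are log1p'd first.

    Returns the standardized matrix and the list of zero-variance features
    that were dropped (with a warning).
    """
    if len(features) < 2:
        raise ValueError("standardize requires at least 2 users")
    x = features.astype(float).copy()
    for c in COUNT_FEATURES:
        if c in x.columns:
            x[c] = np.log1p(x[c])
    dropped = [c for c in x.columns if x[c].std(ddof=0) == 0.0]
    for c in dropped:
        warnings.warn(f"zero-variance feature {c!r} dropped", stacklevel=2)
    x = x.drop(columns=dropped)
    if x.empty or x.shape[1] == 0:
        raise ValueError("no informative features remain after dropping constants")
    return (x - x.mean()) / x.std(ddof=0), dropped


@dataclass
class KSelection:
    k: int
    wcss: dict[int, float]
    silhouette: dict[int, float]
    elbow_strength: dict[int, float] = field(default_factory=dict)


def choose_k(x: pd.DataFrame, k_range: range | list[int] = range(2, 9), seed: int = 42) -> KSelection:
    """Elbow selection on the within-cluster sum-of-squares curve.

    The elbow at k is scored by the ratio of successive WCSS drops,
    (WCSS(k-1) - WCSS(k)) / (WCSS(k) - WCSS(k+1)): a sharp bend makes the
    drop before k much larger than the drop after it. This ratio form of
    the second difference is scale-free, so a single dominant first split
    cannot mask a later elbow (which the raw second difference is prone
    to). WCSS is additionally evaluated at min(k_range)-1 and
    max(k_range)+1 so the score is defined at the range's endpoints.
    """
    ks = sorted(k_range)
    n = len(x)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(x.to_numpy().std(axis=0), 0):
        raise ValueError("degenerate data: all points identical")
    eval_ks = [max(1, ks[0] - 1)] + ks + [ks[-1] + 1]
    wcss: dict[int, float] = {}
    sil: dict[int, float] = {}
    for k in dict.fromkeys(eval_ks):
        labels, _, inertia = _fit_kmeans(x.to_numpy(), k, seed)
        wcss[k] = inertia
        if k in ks and 2 <= k <= n - 1:
            sil[k] = float(silhouette_score(x, labels))
    eps = 1e-9 * wcss[min(wcss)]
    strength = {
        k: (wcss[k - 1] - wcss[k]) / max(wcss[k] - wcss[k + 1], eps)
        for k in ks
        if k - 1 in wcss and k + 1 in wcss
    }
    best = max(strength, key=lambda k: (strength[k], -k))
    return KSelection(k=best, wcss=wcss, silhouette=sil, elbow_strength=strength)


def _fit_kmeans(arr: np.ndarray, k: int, seed: int):
    if k == 1:
        centroid = arr.mean(axis=0, keepdims=True)
        inertia = float(((arr - centroid) ** 2).sum())
        return np.zeros(len(arr), dtype=int), centroid, inertia
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(arr)
    return labels, km.cluster_centers_, float(km.inertia_)


def kmeans_cluster(
    x: pd.DataFrame, k: int, seed: int = 42
) -> tuple[pd.Series, pd.DataFrame]:
    """Lloyd k-means with k-means++ seeding; deterministic for a fixed seed.

    Returns (labels indexed by user_id, centroids in standardized space).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels, centers, _ = _fit_kmeans(x.to_numpy(), k, seed)
    return (
        pd.Series(labels, index=x.index, name="cluster_index"),
        pd.DataFrame(centers, columns=x.columns),
    )


def cluster_centroids(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster feature means on the *original* scale."""
    return features.groupby(labels).mean().sort_index()


def _minmax(s: pd.Series) -> pd.Series:
    span = s.max() - s.min()
    if span == 0:
        return pd.Series(0.5, index=s.index)
    return (s - s.min()) / span


def name_clusters(centroids: pd.DataFrame) -> dict[int, str]:
    """Assign each of five clusters one archetype by its centroid profile.

    Ordered rules on original-scale centroids (counts compared on log1p
    scale, min-max normalized across centroids):

    1. influential — largest posts+followers composite;
    2. mingler — among the rest, most followers with below-median posts;
    3. inactive — among the rest, smallest composite of all five features;
    4. platform vs general — the remaining two split by mrank (higher =
       platform).

    Raises :class:`ArchetypeCollision` if the rules cannot give every
    cluster a distinct name (e.g. identical centroids).
    """
    if len(centroids) != 5:
        raise ValueError("archetype naming requires exactly 5 clusters")
    c = centroids.copy()
    for col in COUNT_FEATURES:
        c[col] = np.log1p(c[col])
    norm = c.apply(_minmax)

    names: dict[int, str] = {}
    remaining = list(c.index)

    def claim(idx, name):
        names[idx] = name
        remaining.remove(idx)

    influence = norm["posts_count"] + norm["followers_count"]
    claim(_argmax(influence, remaining), "influential")

    posts_median = c.loc[remaining, "posts_count"].median()
    candidates = [i for i in remaining if c.loc[i, "posts_count"] <= posts_median]
    pool = candidates or remaining
    claim(_argmax(norm.loc[pool, "followers_count"], pool), "mingler")

    overall = norm[list(c.columns)].sum(axis=1)
    claim(_argmin(overall, remaining), "inactive")

    a, b = remaining
    if c.loc[a, "mrank"] == c.loc[b, "mrank"]:
        raise ArchetypeCollision(
            f"clusters {a} and {b} tie on mrank; platform/general unresolved"
        )
    hi, lo = (a, b) if c.loc[a, "mrank"] > c.loc[b, "mrank"] else (b, a)
    names[hi] = "platform"
    names[lo] = "general"

    assert sorted(names.values()) == sorted(ARCHETYPES)
    return names


class ArchetypeCollision(ValueError):
    """The naming rules could not give every cluster a distinct archetype."""


def _argmax(s: pd.Series, pool: list) -> int:
    s = s.loc[pool]
    return int(s[s == s.max()].index.min())


def _argmin(s: pd.Series, pool: list) -> int:
    s = s.loc[pool]
    return int(s[s == s.min()].index.min())


def assign_archetypes(
    labels: pd.Series, names: dict[int, str] | None
) -> pd.DataFrame:
    """clusters table: user_id, cluster_index, archetype (blank if unnamed)."""
    out = labels.rename("cluster_index").reset_index()
    out["archetype"] = (
        out["cluster_index"].map(names) if names else pd.Series([None] * len(out))
    )
    return out


def topic_cluster_crosstab(
    assignments: pd.DataFrame, posts_df: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table of archetype (or cluster) x topic over posts.

    Posts by users without a cluster assignment are excluded (count
    logged). Returns (counts, row-normalized shares); row sums of counts
    equal per-archetype post counts.
    """
    key = "archetype" if assignments["archetype"].notna().any() else "cluster_index"
    merged = posts_df.merge(
        assignments[["user_id", key]],
        left_on="author_id",
        right_on="user_id",
        how="left",
    )
    unassigned = merged[key].isna().sum()
    if unassigned:
        log.info("crosstab: excluded %d posts by unclustered authors", unassigned)
    merged = merged.dropna(subset=[key, "topic"])
    counts = pd.crosstab(merged[key], merged["topic"])
    shares = counts.div(counts.sum(axis=1), axis=0)
    return counts, shares
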
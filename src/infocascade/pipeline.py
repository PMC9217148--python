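"""Pipeline orchestration and report assembly.

Stages run in order: parse -> build trees -> metrics -> typology ->
clustering -> associations -> report. Each stage writes its output table
and logs row counts, so conservation (input rows = accepted + rejected)
can be audited from the logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel

from . import chains, io, stats, trees, typology, users as ua
from .models import Dataset

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    posts_path: str
    users_path: str
    reposts_path: str
    out_dir: str
    fmt: str = "csv"
    separator: str = "//"
    seed: int = 42
    k: Optional[int] = None  # None = elbow-selected
    k_range: tuple[int, int] = (2, 8)


@dataclass
class PipelineResult:
    dataset: Dataset
    read_report: io.ReadReport
    parsed: dict[str, chains.ResolutionResult]
    metrics: pd.DataFrame
    clusters: Optional[pd.DataFrame]
    centroids: Optional[pd.DataFrame]
    crosstab: Optional[pd.DataFrame]
    correlations: pd.DataFrame
    group_summary: pd.DataFrame
    timebins: pd.DataFrame
    chosen_k: Optional[int]
    report_text: str


def parse_stage(ds: Dataset, separator: str = "//") -> dict[str, chains.ResolutionResult]:
    """Resolve parents for every root post's repost set."""
    results = {}
    by_root = ds.reposts_by_root()
    for post in ds.posts:
        recs = by_root.get(post.post_id, [])
        results[post.post_id] = chains.resolve_parents(
            recs, root_post_id=post.post_id, separator=separator
        )
    n_orphans = sum(len(r.orphans) for r in results.values())
    log.info("parse: %d reposts, %d orphans dropped", len(ds.reposts), n_orphans)
    return results


def metrics_stage(
    ds: Dataset, parsed: dict[str, chains.ResolutionResult]
) -> pd.DataFrame:
    """Build each tree, compute metrics and classify its structure."""
    rows = []
    for post in ds.posts:
        res = parsed[post.post_id]
        tree = trees.build_tree(post, res.edges, res.parsed)
        m = trees.compute_metrics(tree)
        m.net_type = typology.classify_network(tree).net_type
        rows.append(m)
    table = trees.metrics_table(rows)
    log.info("metrics: %d cascades", len(table))
    return table


def clustering_stage(
    ds: Dataset, seed: int = 42, k: Optional[int] = None, k_range=(2, 8)
):
    """Standardize authority features, pick k, cluster and name archetypes."""
    feats = ua.authority_features(ds.users_df())
    x, dropped = ua.standardize(feats)
    if k is None:
        sel = ua.choose_k(x, range(k_range[0], k_range[1] + 1), seed=seed)
        k = sel.k
        log.info("elbow-selected k=%d", k)
    labels, _ = ua.kmeans_cluster(x, k, seed=seed)
    centroids = ua.cluster_centroids(feats, labels)
    names = None
    if k == 5:
        try:
            names = ua.name_clusters(centroids)
        except ua.ArchetypeCollision as exc:
            log.warning("archetype naming unresolved: %s", exc)
    assignments = ua.assign_archetypes(labels, names)
    return assignments, centroids, k


def association_stage(ds: Dataset, metrics: pd.DataFrame):
    """Join cascade metrics to creator features; correlations + summaries."""
    posts = ds.posts_df()
    users_df = ds.users_df()
    joined = (
        metrics.merge(posts[["post_id", "author_id", "topic"]], on="post_id")
        .merge(users_df, left_on="author_id", right_on="user_id", how="left")
    )
    corr = stats.correlation_matrix(joined)
    summary = stats.group_summary(
        joined, ["scale", "depth", "max_width", "avg_width", "speed"], "topic"
    )
    timebins = stats.time_binned_aggregate(posts)
    return corr, summary, timebins


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, report = io.read_dataset(
        cfg.posts_path, cfg.users_path, cfg.reposts_path, fmt=cfg.fmt
    )
    parsed = parse_stage(ds, cfg.separator)
    _write_parsed(parsed, out)
    metrics = metrics_stage(ds, parsed)
    metrics.to_csv(out / "cascade_metrics.csv", index=False)

    clusters = centroids = crosstab = None
    chosen_k = None
    if len(ds.users) >= 3:
        clusters, centroids, chosen_k = clustering_stage(
            ds, seed=cfg.seed, k=cfg.k, k_range=cfg.k_range
        )
        clusters.to_csv(out / "clusters.csv", index=False)
        centroids.to_csv(out / "centroids.csv")
        counts, shares = ua.topic_cluster_crosstab(clusters, ds.posts_df())
        crosstab = counts
        counts.to_csv(out / "crosstab.csv")

    corr, summary, timebins = association_stage(ds, metrics)
    corr.to_csv(out / "correlations.csv", index=False)
    summary.to_csv(out / "group_summary.csv", index=False)
    timebins.to_csv(out / "timebins.csv", index=False)

    text = make_report(ds, metrics, clusters, corr)
    (out / "report.md").write_text(text, encoding="utf-8")
    return PipelineResult(
        dataset=ds,
        read_report=report,
        parsed=parsed,
        metrics=metrics,
        clusters=clusters,
        centroids=centroids,
        crosstab=crosstab,
        correlations=corr,
        group_summary=summary,
        timebins=timebins,
        chosen_k=chosen_k,
        report_text=text,
    )


def _write_parsed(parsed: dict[str, chains.ResolutionResult], out: Path) -> None:
    rows = []
    orphans = []
    for root, res in parsed.items():
        for p in res.parsed:
            rows.append(
                {
                    "repost_id": p.repost_id,
                    "root_post_id": root,
                    "level": p.level,
                    "resolved_parent": p.resolved_parent,
                }
            )
        for o in res.orphans:
            orphans.append(
                {
                    "repost_id": o.repost_id,
                    "root_post_id": root,
                    "level": o.level,
                    "reason": o.reason,
                }
            )
    pd.DataFrame(
        rows, columns=["repost_id", "root_post_id", "level", "resolved_parent"]
    ).to_csv(out / "parsed_reposts.csv", index=False)
    pd.DataFrame(
        orphans, columns=["repost_id", "root_post_id", "level", "reason"]
    ).to_csv(out / "orphans.csv", index=False)


def percent(numerator: int, denominator: int) -> str:
    """Share as a percentage string with two decimals, half-up rounding."""
    if denominator == 0:
        return "n/a"
    value = Decimal(numerator) / Decimal(denominator) * 100
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _share_table(series: pd.Series, title: str) -> list[str]:
    total = int(series.sum())
    lines = [f"## {title}", "", "| category | n | share |", "|---|---|---|"]
    for cat, n in series.sort_values(ascending=False).items():
        lines.append(f"| {cat} | {int(n)} | {percent(int(n), total)}% |")
    lines.append(f"| total | {total} | 100.00% |")
    lines.append("")
    return lines


def make_report(
    ds: Dataset,
    metrics: pd.DataFrame,
    clusters: Optional[pd.DataFrame],
    correlations: pd.DataFrame,
) -> str:
    """Assemble the summary document (descriptive grid, share tables,
    cluster summary, correlation grid)."""
    lines = ["# Dissemination analysis report", ""]
    lines.append(
        f"Posts: {len(ds.posts)}; users: {len(ds.users)}; reposts: {len(ds.reposts)}; "
        f"missing user references: {len(ds.missing_users)}"
    )
    lines.append("")

    disseminated = metrics[metrics["scale"] > 0]
    lines.append("## Dissemination measures")
    lines.append("")
    if disseminated.empty:
        lines.append("no cascades (no post was ever reposted)")
        lines.append("")
    else:
        lines += ["| measure | mean (SD) | maximum |", "|---|---|---|"]
        for col in ("scale", "depth", "max_width", "avg_width", "speed"):
            vals = disseminated[col].dropna()
            lines.append(
                f"| {col} | {vals.mean():.1f} ({vals.std(ddof=1):.2f}) | {vals.max():.1f} |"
            )
        lines.append("")

    posts_df = ds.posts_df()
    topic_counts = posts_df["topic"].value_counts(dropna=True)
    if topic_counts.empty:
        lines += ["## Topic shares", "", "no topic-labeled posts", ""]
    else:
        lines += _share_table(topic_counts, "Topic shares")

    users_df = ds.users_df()
    if not users_df.empty:
        bands = pd.cut(
            users_df["urank"],
            bins=[-1, 13, 27, 41, 48],
            labels=["0-13", "14-27", "28-41", "42-48"],
        )
        lines += _share_table(
            bands.value_counts().sort_index(), "User activity levels (urank bands)"
        )

    nets = metrics.loc[metrics["net_type"] != "undisseminated", "net_type"].value_counts()
    if nets.empty:
        lines += ["## Network types", "", "no cascades", ""]
    else:
        lines += _share_table(nets, "Network types")

    if clusters is not None and not clusters.empty:
        key = "archetype" if clusters["archetype"].notna().any() else "cluster_index"
        lines += _share_table(clusters[key].value_counts(), "User clusters")

    lines.append("## Topology x authority correlations (Spearman)")
    lines.append("")
    if correlations["rho"].notna().any():
        grid = correlations.pivot(index="metric", columns="feature", values="rho")
        lines.append("| metric | " + " | ".join(grid.columns) + " |")
        lines.append("|" + "---|" * (len(grid.columns) + 1))
        for metric, row in grid.iterrows():
            cells = " | ".join(
                "" if pd.isna(v) else f"{v:.3f}" for v in row
            )
            lines.append(f"| {metric} | {cells} |")
    else:
        lines.append("not enough complete cases")
    lines.append("")
    return "\n".join(lines)
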
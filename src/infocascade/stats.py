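"""Statistical summaries: rank correlations between cascade topology and
creator authority, per-topic descriptives with 95% CIs, time-binned topic
and sentiment aggregates, and Krippendorff's alpha for coder reliability.

Spearman's rho is the Pearson correlation of midranks, with a two-sided p
from the t approximation; pairwise complete cases are used and raw
(unadjusted) p-values are reported, with an optional Benjamini-Hochberg
column. Krippendorff's alpha is computed from the coincidence matrix with
the nominal distance, handling missing labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Table layout: topology metrics (rows) x authority features (columns)
TOPOLOGY_METRICS = ("scale", "max_width", "avg_width", "depth", "speed")
AUTHORITY_COLUMNS = (
    "posts_count",
    "followers_count",
    "following_count",
    "mrank",
    "urank",
)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: Optional[float]
    p_value: Optional[float]
    n: int


@dataclass
class ReliabilityResult:
    alpha: float
    n_items: int
    n_coders: int
    metric: str = "nominal"


def spearman(x: Sequence[float], y: Sequence[float], pair=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    Requires >= 3 paired finite observations; a constant vector makes rho
    undefined (reported as missing).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = len(xa)
    if n < 3:
        return CorrelationResult(pair, None, None, n)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(pair, None, None, n)
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult(pair, float(rho), float(p), n)


def correlation_matrix(
    table: pd.DataFrame,
    rows: Sequence[str] = TOPOLOGY_METRICS,
    cols: Sequence[str] = AUTHORITY_COLUMNS,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Grid of Spearman correlations, one row per (topology, authority) pair.

    Complete cases are taken per pair; cells with fewer than 3 complete
    cases are reported with missing rho/p. Columns: metric, feature, rho,
    p_value, n and (optionally) p_bh.
    """
    records = []
    for r in rows:
        for c in cols:
            res = spearman(table[r], table[c], pair=(r, c))
            records.append(
                {
                    "metric": r,
                    "feature": c,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    out = pd.DataFrame(records)
    if bh_adjust:
        out["p_bh"] = _benjamini_hochberg(out["p_value"])
    return out


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    mask = p.notna()
    adj = pd.Series(np.nan, index=p.index)
    if mask.any():
        from statsmodels.stats.multitest import multipletests

        adj.loc[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def group_summary(
    table: pd.DataFrame,
    value_cols: Sequence[str],
    group_col: str = "topic",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-group mean, SD, max and t-based CI of the mean for each column.

    CI = mean +/- t(1-(1-conf)/2, n-1) * SD / sqrt(n); missing for
    single-row groups. Sample SD (ddof=1).
    """
    rows = []
    for group, sub in table.groupby(group_col, dropna=False):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else math.nan
            if n > 1:
                half = sps.t.ppf(1 - (1 - conf) / 2, n - 1) * sd / math.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = math.nan
            rows.append(
                {
                    "group": group,
                    "variable": col,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "max": float(vals.max()),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def time_binned_aggregate(
    posts_df: pd.DataFrame, freq: str = "W"
) -> pd.DataFrame:
    """Per-ISO-week (Monday-anchored), per-topic post counts and mean sentiment.

    Counts conserve the total number of topic-labeled posts; the sentiment
    column is omitted when absent or entirely missing.
    """
    df = posts_df.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["week"] = (ts - pd.to_timedelta(ts.dt.weekday, unit="D")).dt.normalize()
    has_sent = "sentiment" in df.columns and df["sentiment"].notna().any()
    grouped = df.groupby(["week", "topic"], dropna=False)
    out = grouped.size().rename("n_posts").reset_index()
    if has_sent:
        out = out.merge(
            grouped["sentiment"].mean().rename("mean_sentiment").reset_index(),
            on=["week", "topic"],
        )
    return out


def krippendorff_alpha(
    labels: pd.DataFrame | np.ndarray, metric: str = "nominal"
) -> ReliabilityResult:
    """Krippendorff's alpha from the coincidence matrix (nominal distance).

    ``labels`` is an items x coders grid of categorical labels; missing
    entries (NaN/None) are allowed. alpha = 1 - D_o/D_e where D_o and D_e
    are the observed and expected disagreement; exactly 1 under perfect
    agreement. Items labeled by fewer than two coders carry no pairs; if
    no item is multiply coded, alpha is undefined.
    """
    if metric != "nominal":
        raise NotImplementedError("only the nominal metric is implemented")
    grid = pd.DataFrame(labels)
    if grid.shape[1] < 2 or grid.shape[0] < 2:
        raise ValueError("need >= 2 coders and >= 2 items")

    values = sorted({v for v in grid.to_numpy().ravel() if not _is_missing(v)})
    idx = {v: i for i, v in enumerate(values)}
    k = len(values)
    o = np.zeros((k, k))
    for _, row in grid.iterrows():
        present = [v for v in row if not _is_missing(v)]
        m = len(present)
        if m < 2:
            continue
        counts = np.zeros(k)
        for v in present:
            counts[idx[v]] += 1
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)

    n_total = o.sum()
    if n_total == 0:
        raise ValueError("no multiply-coded items: alpha undefined")
    nc = o.sum(axis=1)
    d_o = n_total - np.trace(o)  # off-diagonal mass = observed disagreement
    d_e = (n_total**2 - (nc**2).sum()) / (n_total - 1)
    alpha = 1.0 if d_e == 0 else 1.0 - d_o / d_e
    return ReliabilityResult(
        alpha=float(alpha),
        n_items=int(grid.shape[0]),
        n_coders=int(grid.shape[1]),
    )


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))
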
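"""Association statistics: Spearman, summaries, time bins, reliability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from infocascade import stats


def brute_force_spearman(x, y):
    """Independent oracle: Pearson correlation of midranks, from scratch."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def test_perfect_monotone_is_one():
    assert stats.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)


def test_hand_ranked_example():
    res = stats.spearman([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.rho == pytest.approx(brute_force_spearman([1, 2, 3, 4], [2, 1, 4, 3]))
    assert res.rho == pytest.approx(0.6)  # ranks (1,2,3,4) vs (2,1,4,3)


def test_monotone_transform_invariance():
    x = np.array([0.3, 1.1, 2.9, 0.7, 2.0])
    y = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
    assert stats.spearman(x, y).rho == pytest.approx(
        stats.spearman(np.exp(x), y).rho
    )


def test_constant_vector_is_missing():
    res = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.rho is None and res.p_value is None


@given(
    st.lists(st.integers(min_value=0, max_value=5), min_size=4, max_size=30).flatmap(
        lambda xs: st.tuples(
            st.just(xs),
            st.lists(
                st.integers(min_value=0, max_value=5),
                min_size=len(xs),
                max_size=len(xs),
            ),
        )
    )
)
def test_spearman_matches_brute_force_with_ties(xy):
    """Implementation equals the midrank oracle to 1e-12, ties included."""
    x, y = xy
    if len(set(x)) < 2 or len(set(y)) < 2:
        return
    res = stats.spearman(x, y)
    assert res.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)


def test_correlation_matrix_planted_dependence(small_sim):
    """Scale rank-correlates positively with the author's followers by
    construction in the simulator."""
    from infocascade import pipeline

    _, ds, _ = small_sim
    parsed = pipeline.parse_stage(ds)
    metrics = pipeline.metrics_stage(ds, parsed)
    corr, _, _ = pipeline.association_stage(ds, metrics)
    cell = corr[(corr.metric == "scale") & (corr.feature == "followers_count")]
    assert cell.iloc[0]["rho"] > 0


def test_correlation_matrix_too_few_cases_is_missing():
    table = pd.DataFrame(
        {
            "scale": [1.0, 2.0],
            "posts_count": [3.0, 4.0],
        }
    )
    out = stats.correlation_matrix(table, rows=["scale"], cols=["posts_count"])
    assert out.iloc[0][["rho", "p_value"]].isna().all()
    assert out.iloc[0]["n"] == 2


def test_group_summary_hand_example():
    """Values (1,2,3): mean 2, SD 1, CI 2 +/- 4.303/sqrt(3)."""
    table = pd.DataFrame({"topic": ["t"] * 3, "scale": [1.0, 2.0, 3.0]})
    out = stats.group_summary(table, ["scale"], "topic")
    row = out.iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["sd"] == pytest.approx(1.0)
    half = 4.302652729911275 * 1.0 / math.sqrt(3)
    assert row["ci_low"] == pytest.approx(2 - half)
    assert row["ci_high"] == pytest.approx(2 + half)


def test_group_summary_degenerate_groups():
    table = pd.DataFrame(
        {"topic": ["a", "a", "b"], "scale": [5.0, 5.0, 7.0]}
    )
    out = stats.group_summary(table, ["scale"], "topic").set_index("group")
    assert out.loc["a", "ci_low"] == out.loc["a", "ci_high"] == 5.0  # zero-width
    assert math.isnan(out.loc["b", "ci_low"])  # single row -> no CI


def test_group_summary_ci_coverage():
    """The t-interval covers the true mean at ~95% over replicates."""
    rng = np.random.default_rng(4)
    mu, hits, reps = 3.0, 0, 200
    for _ in range(reps):
        table = pd.DataFrame({"g": ["x"] * 15, "v": rng.normal(mu, 2.0, 15)})
        row = stats.group_summary(table, ["v"], "g").iloc[0]
        hits += row["ci_low"] <= mu <= row["ci_high"]
    se = math.sqrt(0.95 * 0.05 / reps)
    assert abs(hits / reps - 0.95) < 3 * se + 1e-9


def test_time_bins_single_week():
    posts = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(
                ["2020-03-02T10:00", "2020-03-04T11:00", "2020-03-08T09:00"]
            ),
            "topic": ["a", "a", "b"],
            "sentiment": [0.2, 0.4, 0.9],
        }
    )
    out = stats.time_binned_aggregate(posts)
    assert out["n_posts"].sum() == 3
    assert out["week"].nunique() == 1  # Mon 2020-03-02 .. Sun 2020-03-08
    a = out[out.topic == "a"].iloc[0]
    assert a["mean_sentiment"] == pytest.approx(0.3)


def test_time_bins_conserve_totals_and_omit_absent_sentiment():
    rng = np.random.default_rng(5)
    posts = pd.DataFrame(
        {
            "timestamp": pd.to_datetime("2020-01-06")
            + pd.to_timedelta(rng.integers(0, 70, size=500), unit="D"),
            "topic": rng.choice(["a", "b"], size=500),
        }
    )
    out = stats.time_binned_aggregate(posts)
    assert out["n_posts"].sum() == 500
    assert "mean_sentiment" not in out.columns
    assert (out["week"].dt.weekday == 0).all()  # Monday-anchored


# --- Krippendorff's alpha ------------------------------------------------


def coincidence_alpha(grid):
    """Oracle: alpha from an explicitly accumulated coincidence matrix."""
    values = sorted({v for row in grid for v in row if v is not None})
    idx = {v: i for i, v in enumerate(values)}
    k = len(values)
    o = np.zeros((k, k))
    for row in grid:
        present = [v for v in row if v is not None]
        m = len(present)
        if m < 2:
            continue
        for i, a in enumerate(present):
            for j, b in enumerate(present):
                if i != j:
                    o[idx[a], idx[b]] += 1.0 / (m - 1)
    n = o.sum()
    nc = o.sum(axis=1)
    d_o = n - np.trace(o)
    d_e = (n * n - (nc**2).sum()) / (n - 1)
    return 1.0 if d_e == 0 else 1.0 - d_o / d_e


def test_alpha_perfect_agreement_is_exactly_one():
    grid = [["A", "A", "A"], ["B", "B", "B"], ["A", "A", "A"], ["C", "C", "C"]]
    assert stats.krippendorff_alpha(pd.DataFrame(grid)).alpha == 1.0


def test_alpha_matches_coincidence_oracle():
    grid = [["A", "A"], ["A", "B"], ["B", "B"], ["B", "B"]]
    res = stats.krippendorff_alpha(pd.DataFrame(grid))
    assert res.alpha == pytest.approx(coincidence_alpha(grid), abs=1e-12)
    assert res.alpha == pytest.approx(8 / 15)  # hand-built: D_o=2, D_e=30/7


def test_alpha_systematic_disagreement_is_negative():
    grid = [["A", "B"], ["B", "A"], ["A", "B"], ["B", "A"]]
    res = stats.krippendorff_alpha(pd.DataFrame(grid))
    assert res.alpha == pytest.approx(coincidence_alpha(grid), abs=1e-12)
    assert res.alpha < 0


def test_alpha_with_missing_labels_matches_oracle():
    grid = [
        ["A", "A", None, "A"],
        ["B", None, "B", "B"],
        ["A", "B", "A", None],
        [None, None, "C", "C"],
    ]
    res = stats.krippendorff_alpha(pd.DataFrame(grid))
    assert res.alpha == pytest.approx(coincidence_alpha(grid), abs=1e-12)


def test_alpha_label_permutation_invariance():
    grid = [["A", "A"], ["A", "B"], ["B", "B"], ["C", "B"]]
    swapped = [[{"A": "B", "B": "C", "C": "A"}[v] for v in row] for row in grid]
    a1 = stats.krippendorff_alpha(pd.DataFrame(grid)).alpha
    a2 = stats.krippendorff_alpha(pd.DataFrame(swapped)).alpha
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_alpha_undefined_when_all_single_coded():
    grid = [["A", None], [None, "B"], ["A", None]]
    with pytest.raises(ValueError, match="undefined|single"):
        stats.krippendorff_alpha(pd.DataFrame(grid))
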
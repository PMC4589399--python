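"""Nonparametric group comparison of per-subject PET metrics.

With cohorts of 4-9 animals per group, normality is untestable; group
differences in SUVmax, Ki and the individual rate constants are assessed
with the Kruskal-Wallis rank test

    H = [12 / (N (N+1))] * sum_i R_i^2 / n_i - 3 (N+1)

(mid-ranks for ties, divided by the tie correction 1 - sum(t^3 - t)/(N^3 - N)),
with the p-value from the chi-square approximation on (groups - 1) degrees
of freedom, or by exact permutation enumeration for very small samples.
A significant omnibus is followed by Dunn's pairwise z comparisons on the
pooled ranks, Holm-adjusted by default.  Metric association is summarized
by the Pearson R^2.

Measurement tables are tidy DataFrames with columns
``subject``, ``group``, ``metric``, ``value`` (one value per subject and
metric), exchanged on disk as TSV.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "kruskal_wallis",
    "posthoc_pairwise",
    "metric_correlation",
    "run_group_analysis",
    "validate_measurement_table",
]

TABLE_COLUMNS = ("subject", "group", "metric", "value")


@dataclass(frozen=True)
class GroupComparisonResult:
    """Kruskal-Wallis omnibus outcome, optionally with a post-hoc table."""

    h_statistic: float
    p_value: float
    df: int
    method: str  # "chi2" or "exact"
    pairwise: pd.DataFrame | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False


def _rank_sums(values: np.ndarray, sizes: list[int]) -> tuple[np.ndarray, float]:
    """Pooled mid-ranks summed per group, plus the tie term sum(t^3 - t)."""
    ranks = sps.rankdata(values)
    sums = []
    start = 0
    for n in sizes:
        sums.append(ranks[start : start + n].sum())
        start += n
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return np.asarray(sums), tie_term


def _h_statistic(values: np.ndarray, sizes: list[int]) -> float:
    n_total = values.size
    sums, tie_term = _rank_sums(values, sizes)
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(sums**2 / np.asarray(sizes)) - 3.0 * (
        n_total + 1
    )
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all pooled values identical
        return 0.0
    return float(h / correction)


def _exact_permutation_p(values: np.ndarray, sizes: list[int], h_obs: float) -> float:
    """Exact p by enumerating all distinct assignments of values to groups.

    The pooled mid-ranks and tie correction are invariant under
    relabeling, so each assignment only needs its per-group rank sums.
    """
    n_total = values.size
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        return 1.0
    base = 12.0 / (n_total * (n_total + 1))
    inv_sizes = [1.0 / n for n in sizes]
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], g: int, acc: float):
        nonlocal count, total
        if g == len(sizes) - 1:
            r = sum(ranks[i] for i in remaining)
            h = (base * (acc + r * r * inv_sizes[g]) - 3.0 * (n_total + 1)) / correction
            total += 1
            if h >= h_obs - 1e-9:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            chosen = set(combo)
            r = sum(ranks[i] for i in combo)
            rest = tuple(i for i in remaining if i not in chosen)
            recurse(rest, g + 1, acc + r * r * inv_sizes[g])

    recurse(tuple(range(n_total)), 0, 0.0)
    return count / total


def kruskal_wallis(
    groups: list[np.ndarray], method: str = "auto", exact_limit: int = 10
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus test across independent samples.

    ``method`` is ``"chi2"`` (chi-square approximation), ``"exact"``
    (full permutation enumeration) or ``"auto"`` (exact when the pooled
    sample has at most ``exact_limit`` observations).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must contain at least one observation")
    sizes = [g.size for g in groups]
    values = np.concatenate(groups)
    h = _h_statistic(values, sizes)
    df = len(groups) - 1
    if method == "auto":
        method = "exact" if values.size <= exact_limit else "chi2"
    if method == "exact":
        p = _exact_permutation_p(values, sizes, h)
    elif method == "chi2":
        p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparisonResult(h_statistic=h, p_value=p, df=df, method=method)


def posthoc_pairwise(
    groups: list[np.ndarray], labels: list[str] | None = None, adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise comparisons on the pooled ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with tie term T = sum(t^3 - t); two-sided normal p-values adjusted by
    ``adjust`` ("holm", "bonferroni" or "none").  Rows are ordered by the
    lexicographically sorted label pair.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("one label per group required")
    sizes = [g.size for g in groups]
    n_total = sum(sizes)
    values = np.concatenate(groups)
    sums, tie_term = _rank_sums(values, sizes)
    mean_ranks = sums / np.asarray(sizes)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    order = sorted(range(len(groups)), key=lambda i: labels[i])
    rows = []
    for i, j in itertools.combinations(order, 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])
    if adjust == "none":
        df["p_adjusted"] = df["p_value"]
    elif adjust in ("holm", "bonferroni"):
        df["p_adjusted"] = multipletests(df["p_value"], method=adjust)[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def validate_measurement_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "metric"])
    if dup.any():
        raise ValueError("one value per (subject, metric) required")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    return table


def metric_correlation(
    table: pd.DataFrame,
    metric_a: str,
    metric_b: str,
    groups: list[str] | None = None,
) -> CorrelationResult:
    """Pearson R^2 (and two-sided p) between two metrics across subjects.

    Values are paired per subject; ``groups`` optionally restricts the
    subjects to the given group labels.  Constant input yields a flagged
    degenerate result (undefined correlation).
    """
    validate_measurement_table(table)
    sub = table[table["metric"].isin([metric_a, metric_b])]
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    wide = sub.pivot(index="subject", columns="metric", values="value").dropna()
    if metric_a not in wide.columns or metric_b not in wide.columns or len(wide) < 3:
        raise ValueError("need at least 3 subjects with both metrics")
    x = wide[metric_a].to_numpy(dtype=float)
    y = wide[metric_b].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r_squared=float("nan"), p_value=float("nan"), n=len(wide), degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r_squared=float(r * r), p_value=float(p), n=len(wide))


def _analyze_groups(
    sub: pd.DataFrame, labels: list[str], alpha: float, adjust: str, kw_method: str
) -> dict:
    groups = [sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float) for g in labels]
    omnibus = kruskal_wallis(groups, method=kw_method)
    entry = {
        "groups": {
            g: {
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
            for g, v in zip(labels, groups)
        },
        "omnibus": {
            "H": omnibus.h_statistic,
            "df": omnibus.df,
            "p_value": omnibus.p_value,
            "method": omnibus.method,
        },
        "pairwise": None,
    }
    if omnibus.p_value < alpha and len(labels) >= 3:
        entry["pairwise"] = posthoc_pairwise(groups, labels, adjust=adjust).to_dict(
            orient="records"
        )
    return entry


def run_group_analysis(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    alpha: float = 0.05,
    adjust: str = "holm",
    kw_method: str = "chi2",
    contrasts: dict[str, list[str]] | None = None,
) -> dict:
    """Full comparison report: per-metric summaries, omnibus test, post-hoc.

    For each metric the report carries group mean +/- SD, the
    Kruskal-Wallis omnibus over all groups, and — only when the omnibus
    p < alpha — the pairwise Dunn table.  ``contrasts`` optionally names
    subsets of groups to compare separately (e.g. lesion types at one
    body location, or one lesion type across locations); each contrast
    gets its own Kruskal-Wallis run (plus post-hoc for three or more
    groups), mirroring how small-cohort studies report same-location and
    same-lesion comparisons.  Returns a JSON-serializable dict.
    """
    validate_measurement_table(table)
    if metrics is None:
        metrics = sorted(table["metric"].unique())
    report: dict = {"alpha": alpha, "metrics": {}}
    for metric in metrics:
        sub = table[table["metric"] == metric]
        if sub.empty:
            raise ValueError(f"metric {metric!r} absent from the table")
        labels = sorted(sub["group"].unique())
        if len(labels) < 2:
            raise ValueError(f"metric {metric!r}: missing contrast groups (need >= 2)")
        entry = _analyze_groups(sub, labels, alpha, adjust, kw_method)
        if contrasts:
            entry["contrasts"] = {}
            for name, wanted in contrasts.items():
                missing = sorted(set(wanted) - set(labels))
                if missing:
                    raise ValueError(f"contrast {name!r}: missing groups {missing}")
                entry["contrasts"][name] = _analyze_groups(
                    sub[sub["group"].isin(wanted)], sorted(wanted), alpha, adjust, kw_method
                )
        report["metrics"][metric] = entry
    return report
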
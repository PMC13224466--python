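"""Group-comparison summaries shared by all quantification stages.

Works on a long "group table": one row per (group, animal, metric, value).
Summaries are mean ± sample SD (n − 1 denominator) per group per metric.
Omnibus comparisons are one-way ANOVA with Tukey's HSD post hoc, or the
Kruskal–Wallis test with Dunn's post hoc z-tests (tie-corrected,
Bonferroni-adjusted).  ANOVA/Tukey and Kruskal–Wallis delegate to scipy
and statsmodels; the Dunn pairwise step is computed here from pooled
ranks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED_COLUMNS = ("group", "animal_id", "metric", "value")


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"group table is missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["animal_id", "metric"])
    if dup.any():
        raise ValueError("group table holds more than one value per (animal, metric)")


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD (and n) per group per metric; invariant to row order.

    SD uses the sample (n − 1) denominator and is reported as missing for
    a single-animal group, never as zero.
    """
    _check_table(table)
    out = (
        table.groupby(["metric", "group"], sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based post hoc z-tests with tie correction.

    For groups i, j:  z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))
    where T = Σ(t³ − t) / (12(N − 1)) corrects for tied ranks.  Two-sided
    p-values are Bonferroni-adjusted over all pairs.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in combinations(labels, 2):
        n_a, n_b = groups[a].size, groups[b].size
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n_a + 1.0 / n_b))
        diff = mean_ranks[a] - mean_ranks[b]
        z = 0.0 if se == 0 else diff / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": z,
                "difference": diff,
                "p_adjusted": min(1.0, p * n_pairs),
            }
        )
    return rows


def compare_groups(
    table: pd.DataFrame,
    test: Literal["anova_tukey", "kruskal_dunn"] = "anova_tukey",
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-metric omnibus test plus pairwise post hoc comparisons.

    Returns, per metric, the omnibus statistic and p-value and a list of
    pairwise records (group pair, effect/statistic, adjusted p).
    """
    _check_table(table)
    results: dict[str, dict] = {}
    for metric, sub in table.groupby("metric", sort=True):
        groups = {
            str(g): np.asarray(vals["value"], dtype=float)
            for g, vals in sub.groupby("group", sort=True)
        }
        if len(groups) < 2:
            raise ValueError(f"metric {metric!r} has fewer than 2 groups")
        samples = list(groups.values())
        pooled = np.concatenate(samples)
        degenerate = np.ptp(pooled) == 0  # no variation anywhere: tests are no-ops
        if test == "anova_tukey":
            stat, p = (0.0, 1.0) if degenerate else stats.f_oneway(*samples)
            tukey = pairwise_tukeyhsd(
                endog=sub["value"].to_numpy(dtype=float),
                groups=sub["group"].to_numpy(dtype=str),
                alpha=alpha,
            )
            pairwise = [
                {
                    "group_a": str(a),
                    "group_b": str(b),
                    "difference": float(diff),
                    "p_adjusted": float(padj),
                }
                for (a, b), diff, padj in zip(
                    combinations(tukey.groupsunique, 2),
                    tukey.meandiffs,
                    tukey.pvalues,
                )
            ]
        elif test == "kruskal_dunn":
            stat, p = (0.0, 1.0) if degenerate else stats.kruskal(*samples)
            pairwise = _dunn_pairwise(groups)
        else:
            raise ValueError(f"unknown test {test!r}")
        results[str(metric)] = {
            "test": test,
            "statistic": float(stat),
            "p_value": float(p),
            "pairwise": pairwise,
        }
    return results
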
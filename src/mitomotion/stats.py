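"""Nonparametric group comparison: Kruskal–Wallis + Dunn's post hoc test.

Metrics are compared across treatment conditions with the tie-corrected
Kruskal–Wallis omnibus test (chi-square approximation, k−1 degrees of
freedom), followed by Dunn's z tests on a small set of *preselected*
condition pairs.  The multiplicity correction is Bonferroni over the
preselected pairs only — ``p_adjusted = min(1, p_raw × n_pairs)`` — not
over all k(k−1)/2 pairs, matching the common practice of comparing each
treatment against a single reference condition.

Per-mitochondrion observations (per-track displacement and speed,
per-particle area/Feret/aspect ratio) enter the tests pooled across ROIs,
so n is in the thousands; the per-ROI motile fraction enters with one
observation per ROI.  The chi-square approximation is standard but only
trustworthy with at least ~5 observations per group.

Significance tiers: ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001,
``****`` p<0.0001, ``ns`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "PairResult",
    "kruskal_wallis",
    "dunn_preselected",
    "compare_conditions",
    "significance_tier",
]


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    tier: str


@dataclass
class GroupComparison:
    metric: str
    groups: dict[str, np.ndarray]
    h_statistic: float
    p_omnibus: float
    pairs: list[PairResult]


def significance_tier(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over tied groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    H = [12/(N(N+1)) Σ nᵢ R̄ᵢ²] − 3(N+1), divided by the tie-correction
    factor 1 − Σ(t³−t)/(N³−N).  When every pooled observation is identical
    the statistic is defined as H = 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) == 0 for v in samples.values()):
        raise ValueError("every group needs at least 1 observation")
    pooled = np.concatenate(list(samples.values()))
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for v in samples.values():
        r = ranks[start : start + len(v)]
        h += len(v) * r.mean() ** 2
        start += len(v)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    df = len(samples) - 1
    p = float(sps.chi2.sf(h, df))
    return float(h), p


def dunn_preselected(
    groups: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
) -> list[PairResult]:
    """Dunn's z tests on preselected pairs with Bonferroni over those pairs.

    Ranks are computed once over all observations in all groups;

        z = (R̄ₐ − R̄_b) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/nₐ + 1/n_b)]

    with a two-sided normal p-value, adjusted as min(1, p_raw · |pairs|).
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    unknown = {g for pair in pairs for g in pair} - set(groups)
    if unknown:
        raise KeyError(f"unknown group labels: {sorted(unknown)}")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate(list(samples.values()))
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for k, v in samples.items():
        mean_ranks[k] = float(ranks[start : start + len(v)].mean())
        sizes[k] = len(v)
        start += len(v)
    var_term = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    n_pairs = len(pairs)
    results = []
    for a, b in pairs:
        se = math.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        results.append(
            PairResult(
                group_a=a,
                group_b=b,
                z=float(z),
                p_raw=p_raw,
                p_adjusted=p_adj,
                tier=significance_tier(p_adj),
            )
        )
    return results


def compare_conditions(
    observations: pd.DataFrame,
    metric: str,
    pairs: Sequence[tuple[str, str]],
    value_column: str = "value",
    condition_column: str = "condition",
) -> GroupComparison:
    """Run the omnibus and post hoc tests for one metric.

    ``observations`` is a long-format table with one row per observation
    (per track, per particle, or per ROI for the motile fraction) holding
    at least a condition label and a value column; NaN values (flagged
    missing) are dropped before testing.
    """
    if metric is not None and "metric" in observations.columns:
        observations = observations[observations["metric"] == metric]
    if observations.empty:
        raise ValueError(f"no observations for metric {metric!r}")
    observations = observations.dropna(subset=[value_column])
    groups = {
        str(cond): grp[value_column].to_numpy(dtype=float)
        for cond, grp in observations.groupby(condition_column, sort=True)
    }
    empty = [c for c, v in groups.items() if len(v) == 0]
    if empty or len(groups) < 2:
        raise ValueError(f"metric {metric!r}: need >= 2 non-empty conditions")
    h, p = kruskal_wallis(groups)
    pair_results = dunn_preselected(groups, pairs)
    return GroupComparison(
        metric=metric, groups=groups, h_statistic=h, p_omnibus=p,
        pairs=pair_results,
    )


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to the stats.csv schema (one row per pair)."""
    rows = []
    for comp in comparisons:
        for pr in comp.pairs:
            rows.append(
                {
                    "metric": comp.metric,
                    "pair": f"{pr.group_a} vs {pr.group_b}",
                    "kw_h": comp.h_statistic,
                    "kw_p": comp.p_omnibus,
                    "z": pr.z,
                    "p_raw": pr.p_raw,
                    "p_adjusted": pr.p_adjusted,
                    "tier": pr.tier,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["metric", "pair", "kw_h", "kw_p", "z", "p_raw", "p_adjusted",
                 "tier"],
    )
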
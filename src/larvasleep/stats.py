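"""Group-comparison statistics, written out as explicit formulas.

One-way ANOVA and Tukey's HSD are the workhorse tests for comparing sleep
and activity measures across genotypes or treatments; proportions (e.g.
genotyping ratios) get an exact Clopper-Pearson interval.  The ANOVA sum
of squares decomposition is computed explicitly so every intermediate
(SS_between, SS_within, the df pair) is inspectable, with p-values from
scipy's F and studentized-range distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

__all__ = ["AnovaResult", "ProportionResult", "one_way_anova", "tukey_hsd", "proportion"]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class ProportionResult:
    k: int
    n: int
    estimate: float  # k / n
    ci_low: float
    ci_high: float
    confidence: float

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise AnalysisError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise AnalysisError(f"group {i} has {a.size} observations, need >= 2")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA.

    With k groups of sizes n_i, grand mean x̄ and group means x̄_i:

        SS_between = Σ n_i (x̄_i - x̄)²       df = k - 1
        SS_within  = Σ_i Σ_j (x_ij - x̄_i)²  df = N - k
        F = (SS_between / df_b) / (SS_within / df_w)
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    means = [a.mean() for a in arrs]
    ss_between = float(sum(a.size * (m - grand) ** 2 for a, m in zip(arrs, means)))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            raise AnalysisError("all observations identical; ANOVA degenerate")
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    sems = [a.std(ddof=1) / np.sqrt(a.size) for a in arrs]
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means=tuple(float(m) for m in means),
        group_sems=tuple(float(s) for s in sems),
        ss_between=ss_between,
        ss_within=ss_within,
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tukey (Tukey-Kramer for unequal n) all-pairs comparisons.

    For each pair (i, j) the studentized-range statistic is

        q = |x̄_i - x̄_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))

    with the adjusted p from the studentized-range distribution with k
    groups and N - k error df.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise AnalysisError("labels length must match number of groups")
    n_total = sum(a.size for a in arrs)
    df_w = n_total - k
    means = [a.mean() for a in arrs]
    ms_within = sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)) / df_w
    if ms_within == 0:
        raise AnalysisError("zero within-group variance; Tukey test degenerate")
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        se = np.sqrt(ms_within / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "q_statistic": float(q),
                "p_adj": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame(rows)


def proportion(k: int, n: int, confidence: float = 0.95) -> ProportionResult:
    """Binomial proportion with an exact (Clopper-Pearson) interval."""
    if n <= 0:
        raise AnalysisError("n must be positive")
    if not 0 <= k <= n:
        raise AnalysisError(f"k={k} outside [0, {n}]")
    ci = sps.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return ProportionResult(
        k=int(k),
        n=int(n),
        estimate=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        confidence=confidence,
    )
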
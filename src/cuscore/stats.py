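"""Group-level statistics: summaries, one-way ANOVA (from raw values and from
summary statistics), Bonferroni-corrected pooled-variance pairwise t-tests,
Hedges' g effect sizes, and normal-range impairment classification.

Conventions: sample SD (n-1 denominator) throughout; Hedges' g uses the
pooled SD and the small-sample correction J = 1 - 3/(4N - 9), with the
reference (control) group passed first so patient deficits carry a positive
sign; post hoc tests are Student (pooled-variance) t-tests to match the
pooled-SD convention of g, with Welch available behind a flag.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

GROUP_ORDER = ("HC", "lvPPA", "nfvPPA", "svPPA")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    measure: str
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: int
    p: float
    significant: bool
    g: float


@dataclass(frozen=True)
class PairwiseReport:
    results: list[PairwiseResult]
    n_comparisons: int
    alpha: float
    alpha_adjusted: float  # compared unrounded
    alpha_displayed: float  # rounded to 3 decimals for display


def _group_key(label: str):
    try:
        return (0, GROUP_ORDER.index(label))
    except ValueError:
        return (1, label)


def summarize_groups(
    scores: Sequence, measure: str, groups: Optional[Sequence[str]] = None
) -> list[GroupSummary]:
    """Per-group n / mean / sample-SD for one measure.

    ``scores`` is a sequence of objects with ``group`` and ``measure``
    attributes (e.g. ParticipantScore), or a pandas DataFrame with a
    ``group`` column.
    """
    by_group: dict[str, list[float]] = {}
    if hasattr(scores, "columns"):  # DataFrame
        for group, sub in scores.groupby("group"):
            by_group[group] = list(sub[measure].astype(float))
    else:
        for s in scores:
            by_group.setdefault(s.group, []).append(float(getattr(s, measure)))
    if groups is not None:
        by_group = {g: by_group.get(g, []) for g in groups}
    out = []
    for group in sorted(by_group, key=_group_key):
        values = np.asarray(by_group[group], dtype=float)
        if values.size < 2:
            raise ValueError(f"group {group!r} has n={values.size} < 2 for {measure!r}")
        out.append(
            GroupSummary(group, measure, int(values.size),
                         float(values.mean()), float(values.std(ddof=1)))
        )
    return out


def anova_oneway(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA on raw per-participant values."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    N = sum(g.size for g in groups)
    k = len(groups)
    if all(g.std(ddof=1) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        return AnovaResult(0.0, k - 1, N - k, 1.0)
    F, p = sps.f_oneway(*groups)
    return AnovaResult(float(F), k - 1, N - k, float(p))


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA recovered from printed group summaries (n, mean, SD).

    F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N-k)] with m
    the n-weighted grand mean; algebraically identical to the raw-data ANOVA.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 group summaries")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    sd = np.array([s.sd for s in summaries], dtype=float)
    N = n.sum()
    k = len(summaries)
    grand = float((n * m).sum() / N)
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * sd**2).sum())
    df_b, df_w = k - 1, int(N - k)
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = ms_between / ms_within
    return AnovaResult(float(F), df_b, df_w, float(sps.f.sf(F, df_b, df_w)))


def hedges_g(a: GroupSummary, b: GroupSummary) -> float:
    """Bias-corrected standardized mean difference (a minus b, pooled SD).

    Pass the reference group (HC) first so that a patient deficit on the
    measure comes out positive.
    """
    n_a, n_b = a.n, b.n
    pooled_var = ((n_a - 1) * a.sd**2 + (n_b - 1) * b.sd**2) / (n_a + n_b - 2)
    diff = a.mean - b.mean
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        return math.copysign(float("inf"), diff)
    J = 1 - 3 / (4 * (n_a + n_b) - 9)
    return J * diff / math.sqrt(pooled_var)


def pairwise_ttests(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    measure: str = "value",
    welch: bool = False,
) -> PairwiseReport:
    """All-pairs two-sided t-tests with Bonferroni-adjusted alpha.

    For k groups there are m = k(k-1)/2 comparisons; significance is judged
    against the unrounded alpha/m (displayed rounded to 3 decimals, e.g.
    0.008 for alpha 0.05 over 6 comparisons).
    """
    labels = sorted(values_by_group, key=_group_key)
    m = len(labels) * (len(labels) - 1) // 2
    if m == 0:
        raise ValueError("need >= 2 groups")
    adjusted = alpha / m
    results = []
    for ga, gb in itertools.combinations(labels, 2):
        xa = np.asarray(values_by_group[ga], dtype=float)
        xb = np.asarray(values_by_group[gb], dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"group with n < 2 in pair ({ga}, {gb})")
        tt = sps.ttest_ind(xa, xb, equal_var=not welch)
        df = (
            int(xa.size + xb.size - 2)
            if not welch
            else int(round(float(tt.df)))
        )
        sa = GroupSummary(ga, measure, xa.size, float(xa.mean()), float(xa.std(ddof=1)))
        sb = GroupSummary(gb, measure, xb.size, float(xb.mean()), float(xb.std(ddof=1)))
        p = float(tt.pvalue)
        if math.isnan(p):  # both groups constant and equal
            p = 1.0
        results.append(
            PairwiseResult(
                (ga, gb), float(tt.statistic) if not math.isnan(float(tt.statistic)) else 0.0,
                df, p, p < adjusted, hedges_g(sa, sb),
            )
        )
    return PairwiseReport(results, m, alpha, adjusted, round(adjusted, 3))


def classify_impairment(
    hc: GroupSummary, values: Mapping[str, float], z: float = 1.96
) -> dict[str, bool]:
    """Flag participants whose score falls below the control normal range.

    The normal range is the control mean +/- z*SD of the control
    *distribution* (z = 1.96 covers the central 95%); a participant is
    impaired when strictly below the lower bound (one-sided: low
    informativeness is the deficit direction).
    """
    lower = hc.mean - z * hc.sd
    return {pid: bool(v < lower) for pid, v in values.items()}
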
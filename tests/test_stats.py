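"""Group statistics: ANOVA (raw and summary forms), Hedges' g, pairwise
tests, impairment classification."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuscore import reference
from cuscore.stats import (
    GroupSummary,
    anova_from_summary,
    anova_oneway,
    classify_impairment,
    hedges_g,
    pairwise_ttests,
    summarize_groups,
)


def _summary(group, n, mean, sd, measure="v"):
    return GroupSummary(group, measure, n, mean, sd)


def test_summarize_groups_uses_sample_sd():
    class S:  # minimal score-like records
        def __init__(self, group, v):
            self.group, self.v = group, v

    scores = [S("HC", 1.0), S("HC", 3.0), S("svPPA", 2.0), S("svPPA", 2.0)]
    out = {s.group: s for s in summarize_groups(scores, "v")}
    assert out["HC"].mean == 2.0
    assert out["HC"].sd == pytest.approx(math.sqrt(2))
    assert out["svPPA"].sd == 0.0
    with pytest.raises(ValueError):
        summarize_groups([S("HC", 1.0)], "v")


def test_anova_flat_data_gives_zero_f():
    a = anova_oneway({"a": [5, 5, 5], "b": [5, 5, 5]})
    assert a.F == 0.0 and a.p == 1.0


def test_two_group_anova_equals_t_squared():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
    from scipy.stats import ttest_ind

    a = anova_oneway({"x": x, "y": y})
    t = ttest_ind(x, y, equal_var=True)
    assert a.F == pytest.approx(t.statistic**2, rel=1e-12)
    assert a.df_between == 1 and a.df_within == 19


def test_summary_anova_reproduces_published_f():
    a = anova_from_summary(list(reference.CU_ORIGINAL.values()))
    assert (a.df_between, a.df_within) == (3, 97)
    assert a.F == pytest.approx(36.0, abs=0.5)
    assert a.p < 0.001


def test_summary_anova_degenerate_cases():
    same = [_summary("a", 5, 2.0, 0.0), _summary("b", 5, 2.0, 0.0)]
    assert anova_from_summary(same).F == 0.0
    apart = [_summary("a", 5, 1.0, 0.0), _summary("b", 5, 2.0, 0.0)]
    assert math.isinf(anova_from_summary(apart).F)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_summary_anova_matches_raw_anova(seed):
    """The summary-statistic decomposition is exact, not an approximation."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 6))
    data = {
        f"g{i}": rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4),
                            int(rng.integers(2, 40)))
        for i in range(k)
    }
    raw = anova_oneway(data)
    sums = [
        GroupSummary(g, "v", len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for g, v in data.items()
    ]
    from_sum = anova_from_summary(sums)
    assert from_sum.F == pytest.approx(raw.F, abs=1e-10)
    assert from_sum.p == pytest.approx(raw.p, abs=1e-10)
    assert (from_sum.df_between, from_sum.df_within) == (raw.df_between, raw.df_within)


def test_hedges_g_published_values():
    hc_cu = reference.CU_ORIGINAL["HC"]
    assert hedges_g(hc_cu, reference.CU_ORIGINAL["nfvPPA"]) == pytest.approx(1.29, abs=0.01)
    hc_info = reference.INFORMATIVENESS_ORIGINAL["HC"]
    assert hedges_g(hc_info, reference.INFORMATIVENESS_ORIGINAL["nfvPPA"]) == \
        pytest.approx(-0.29, abs=0.01)
    assert hedges_g(hc_cu, hc_cu) == 0.0


def test_hedges_g_antisymmetric_and_shrinks_with_sd():
    a, b = _summary("a", 20, 10.0, 2.0), _summary("b", 15, 7.0, 3.0)
    assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))
    wide_a = _summary("a", 20, 10.0, 4.0)
    wide_b = _summary("b", 15, 7.0, 6.0)
    assert abs(hedges_g(wide_a, wide_b)) < abs(hedges_g(a, b))


def test_pairwise_four_groups():
    rng = np.random.default_rng(3)
    data = {g: rng.normal(i, 1, 12) for i, g in enumerate(["HC", "lvPPA", "nfvPPA", "svPPA"])}
    report = pairwise_ttests(data)
    assert report.n_comparisons == 6
    assert report.alpha_adjusted == pytest.approx(0.05 / 6)
    assert report.alpha_displayed == 0.008
    # Bonferroni-significant results are a subset of unadjusted ones
    for r in report.results:
        if r.significant:
            assert r.p < 0.05


def test_identical_groups_not_significant():
    data = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
    report = pairwise_ttests(data)
    r = report.results[0]
    assert r.p > 0.99 and not r.significant and r.g == 0.0


def test_impairment_normal_range():
    hc = _summary("HC", 31, 20.9, 5.67)
    lower = 20.9 - 1.96 * 5.67
    flags = classify_impairment(hc, {
        "at_bound": lower,       # exactly at bound: not impaired
        "at_mean": 20.9,
        "below": lower - 0.01,
        "above": 40.0,           # high scores are never "impaired"
    })
    assert flags == {
        "at_bound": False, "at_mean": False, "below": True, "above": False,
    }
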
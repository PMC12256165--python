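"""The statistical ladder: normality routing, ANOVA families, exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from obephys.core import InputError
from obephys.stats import (
    bonferroni_alpha,
    bonferroni_alpha_exact,
    fisher_2x2,
    fisher_2xk,
    GroupComparison,
    normality_battery,
    one_way_family,
    sidak_adjust,
    spearman,
    student_t,
    t_pvalue,
    transform_ladder,
    two_way_family,
    variance_explained_normal_fit,
)


# ---------------------------------------------------------------------------
# normality battery and transform ladder
# ---------------------------------------------------------------------------

def test_battery_selects_test_by_sample_size():
    rng = np.random.default_rng(0)
    big = normality_battery(rng.normal(size=100))
    small = normality_battery(rng.normal(size=6))
    assert big["test"] == "dagostino_pearson"
    assert small["test"] == "shapiro_wilk"
    with pytest.raises(InputError):
        normality_battery([1.0, 2.0])


def test_battery_type_i_error_is_nominal():
    rng = np.random.default_rng(1)
    rejections = sum(
        not normality_battery(rng.normal(size=100))["normal"] for _ in range(1000)
    )
    assert 0.02 <= rejections / 1000 <= 0.08


def test_battery_detects_lognormal():
    rng = np.random.default_rng(2)
    hits = sum(
        not normality_battery(np.exp(rng.normal(0, 1, 100)))["normal"]
        for _ in range(200)
    )
    assert hits / 200 > 0.9


def test_battery_degenerate_constant_vector():
    out = normality_battery([3.0] * 10)
    assert out["normal"] is False and out["test"] == "degenerate"


def test_variance_explained_by_normal_fit():
    # exact normal quantiles: essentially nothing unexplained
    q = sps.norm.ppf((np.arange(1, 101) - 0.5) / 100)
    assert variance_explained_normal_fit(q) < 0.005
    # gross outliers among normals: fit fails on > 10% of the variance
    rng = np.random.default_rng(3)
    flagged = sum(
        variance_explained_normal_fit(
            np.concatenate([rng.normal(0, 1, 45), rng.normal(25, 1, 5)])
        ) > 0.10
        for _ in range(50)
    )
    assert flagged >= 45
    assert variance_explained_normal_fit(sps.norm.ppf((np.arange(1, 9) - 0.5) / 8)) < 0.05
    with pytest.raises(InputError):
        variance_explained_normal_fit(np.ones(20))


def test_transform_ladder_routing():
    rng = np.random.default_rng(4)
    name, _ = transform_ladder(np.exp(rng.normal(0, 1.5, 200)))
    assert name == "log10"
    name, x = transform_ladder(rng.normal(10, 2, 200))
    assert name == "none"
    bimodal = np.concatenate([rng.normal(-20, 0.3, 100), rng.normal(20, 0.3, 100)])
    name, ranks = transform_ladder(bimodal)
    assert name == "rank"
    assert sorted(ranks) == list(np.arange(1.0, 201.0))


# ---------------------------------------------------------------------------
# one-way family
# ---------------------------------------------------------------------------

def test_one_way_identical_groups_not_significant():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 1, 30)
    res = one_way_family({"a": base, "b": base + 0.0, "c": base.copy()})
    assert res.p > 0.9
    assert all(p > 0.5 for _, p in res.post_hoc)


def test_one_way_power_for_one_sd_shift():
    rng = np.random.default_rng(6)
    hits = 0
    for _ in range(100):
        groups = {
            "a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
            "c": rng.normal(1, 1, 30),
        }
        if one_way_family(groups).p < 0.05:
            hits += 1
    assert hits > 80


def test_kruskal_wallis_tie_corrected_h():
    """Tie-heavy table: H must match the closed form with tie correction."""
    groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 3.0], "c": [3.0, 4.0, 4.0]}
    res = one_way_family(groups)
    assert res.test.startswith("kruskal")
    h_ref, p_ref = sps.kruskal(*groups.values())
    assert res.statistic == pytest.approx(h_ref)
    # independent closed form: H = (12/(N(N+1)) sum n_i rbar_i^2 - 3(N+1)) / (1 - sum(t^3-t)/(N^3-N))
    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    rbars = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
    h = 12.0 / (n_tot * (n_tot + 1)) * sum(3 * rb**2 for rb in rbars) - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    h /= 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    assert res.statistic == pytest.approx(h, rel=1e-12)


def test_one_way_requires_two_values_per_group():
    with pytest.raises(InputError):
        one_way_family({"a": [1.0], "b": [1.0, 2.0]})


# ---------------------------------------------------------------------------
# two-way family
# ---------------------------------------------------------------------------

def _balanced_frame(rng, n=10, shift=0.0):
    rows = []
    for g in ("wpi5", "wpi9", "resident"):
        for t in ("sham", "occluded"):
            mu = shift if t == "occluded" else 0.0
            for v in rng.normal(mu, 1, n):
                rows.append({"value": v, "group": g, "treatment": t})
    return pd.DataFrame(rows)


def test_two_way_null_type_i_close_to_nominal():
    rng = np.random.default_rng(7)
    hits = sum(
        two_way_family(_balanced_frame(rng)).terms["treatment"]["p"] < 0.05
        for _ in range(200)
    )
    assert 2 <= hits <= 20  # ~5% of 200 with slack


def test_two_way_detects_treatment_shift():
    rng = np.random.default_rng(8)
    res = two_way_family(_balanced_frame(rng, n=25, shift=1.0))
    assert res.terms["treatment"]["p"] < 1e-4


def test_rank_two_way_equals_parametric_on_midranks():
    """Brute-force check on a small 3x2 (n=4) table with heavy ties."""
    rng = np.random.default_rng(9)
    df = _balanced_frame(rng, n=4)
    df["value"] = np.round(np.exp(df["value"] * 2), 0)  # skewed + tied
    ranked = df.copy()
    ranked["value"] = sps.rankdata(df["value"], method="average")
    res_rank = two_way_family(df.copy(), use_ladder=True)
    # force the ladder outcome by checking routing went to ranks
    if res_rank.transform == "rank":
        res_param = two_way_family(ranked, use_ladder=False)
        for term in ("group", "treatment", "interaction"):
            assert res_rank.terms[term]["F"] == pytest.approx(
                res_param.terms[term]["F"], rel=1e-9
            )


def test_rank_two_way_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    df = _balanced_frame(rng, n=10)
    # far-separated bimodal data: no standard transform renders this normal
    df["value"] = np.where(df["value"] > 0, 1000.0, 10.0) + rng.normal(0, 0.5, len(df))
    res_a = two_way_family(df.copy())
    assert res_a.transform == "rank"
    df_b = df.copy()
    df_b["value"] = df_b["value"] ** 0.3  # strictly monotone map
    res_b = two_way_family(df_b)
    assert res_b.transform == "rank"
    for term in ("group", "treatment", "interaction"):
        assert res_a.terms[term]["F"] == pytest.approx(
            res_b.terms[term]["F"], rel=1e-9
        )


def test_two_way_empty_cell_is_an_error():
    rng = np.random.default_rng(11)
    df = _balanced_frame(rng)
    df = df[~((df.group == "wpi9") & (df.treatment == "occluded"))]
    with pytest.raises(InputError):
        two_way_family(df)


def test_sidak_adjustment_closed_form():
    assert sidak_adjust(0.05, 3) == pytest.approx(1 - 0.95**3)
    assert sidak_adjust(0.05, 3) == pytest.approx(0.142625)


@settings(deadline=None, max_examples=50)
@given(p=st.floats(0.0, 1.0))
def test_sidak_never_decreases_p(p):
    adj = sidak_adjust(p, 3)
    assert adj >= p - 1e-15
    if 0.0 < p < 1.0:
        assert adj > p


# ---------------------------------------------------------------------------
# exact tests on counts
# ---------------------------------------------------------------------------

def _bruteforce_fisher(a, n1, b, n2):
    """Independent enumeration oracle with math.comb."""
    s = a + b
    denom = math.comb(n1 + n2, s)
    p_obs = math.comb(n1, a) * math.comb(n2, b) / denom
    total = 0.0
    for x in range(max(0, s - n2), min(n1, s) + 1):
        p = math.comb(n1, x) * math.comb(n2, s - x) / denom
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_2x2_invariances():
    p = fisher_2x2(8, 17, 21, 53)
    assert fisher_2x2(21, 53, 8, 17) == pytest.approx(p)          # swap rows
    assert fisher_2x2(17 - 8, 17, 53 - 21, 53) == pytest.approx(p)  # swap cols
    # transposition: successes/failures become group A/B memberships
    assert fisher_2x2(8, 29, 9, 41) == pytest.approx(p)


def test_fisher_2x2_identical_proportions():
    assert fisher_2x2(5, 20, 5, 20) == pytest.approx(1.0)
    assert fisher_2x2(0, 10, 0, 12) == 1.0  # zero margin, by convention


def test_fisher_2x2_agrees_with_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(60):
        n1, n2 = rng.integers(1, 31, 2)
        a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        assert fisher_2x2(a, n1, b, n2) == pytest.approx(
            _bruteforce_fisher(a, n1, b, n2), rel=1e-9
        ), (a, n1, b, n2)


def test_freeman_halton_reduces_to_fisher_2x2():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n1, n2 = rng.integers(1, 25, 2)
        a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        assert fisher_2xk([a, b], [n1, n2]) == pytest.approx(
            fisher_2x2(a, n1, b, n2), rel=1e-9
        ), (a, n1, b, n2)


def test_freeman_halton_identical_columns():
    assert fisher_2xk([4, 4, 4], [10, 10, 10]) == pytest.approx(1.0)


def test_freeman_halton_enumeration_bound():
    with pytest.raises(InputError):
        fisher_2xk([100, 120, 130], [1000, 1000, 1000], max_tables=1000)


def test_bonferroni_alpha():
    assert bonferroni_alpha(0.05, 3) == 0.017
    assert bonferroni_alpha(0.05, 1) == 0.05
    assert bonferroni_alpha(0.05, 5) == 0.01
    assert bonferroni_alpha_exact(0.05, 3) == pytest.approx(0.05 / 3)
    with pytest.raises(InputError):
        bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# t test and Spearman
# ---------------------------------------------------------------------------

def test_student_t_from_samples_and_summary():
    rng = np.random.default_rng(14)
    a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
    t1, df1, p1 = student_t(a, b)
    summ = {
        "mean": (a.mean(), b.mean()),
        "sem": (a.std(ddof=1) / np.sqrt(5), b.std(ddof=1) / np.sqrt(5)),
        "n": (5, 5),
    }
    t2, df2, p2 = student_t(summary=summ)
    assert df1 == df2 == 8
    assert t1 == pytest.approx(t2, rel=1e-9)
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_student_t_identical_groups():
    t, df, p = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_student_t_null_type_i():
    rng = np.random.default_rng(15)
    hits = sum(
        student_t(rng.normal(size=5), rng.normal(size=5))[2] < 0.05
        for _ in range(2000)
    )
    assert 0.03 <= hits / 2000 <= 0.07


def test_spearman_perfect_monotone():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    r, _ = spearman(x, [v**3 for v in x])
    assert r == pytest.approx(1.0)
    r, _ = spearman(x, [-v for v in x])
    assert r == pytest.approx(-1.0)


def test_spearman_exact_permutation_small_n():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 4.0, 3.0, 5.0]
    r_obs = sps.spearmanr(x, y).statistic
    # exact two-sided p by full enumeration of the 5! permutations
    perms = list(itertools.permutations(y))
    count = sum(
        abs(sps.spearmanr(x, p).statistic) >= abs(r_obs) - 1e-12 for p in perms
    )
    r, p = spearman(x, y)
    assert r == pytest.approx(r_obs)
    assert p == pytest.approx(count / len(perms))


def test_spearman_independent_data_centres_on_zero():
    rng = np.random.default_rng(16)
    rs = [spearman(rng.uniform(size=20), rng.uniform(size=20))[0] for _ in range(300)]
    assert abs(np.mean(rs)) < 0.05


def test_spearman_rejects_constant_vector():
    with pytest.raises(InputError):
        spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# model-style interface
# ---------------------------------------------------------------------------

def test_group_comparison_model_interface():
    rng = np.random.default_rng(17)
    df = _balanced_frame(rng, n=8, shift=1.5).rename(columns={"value": "mAHP"})
    df["mAHP"] = np.abs(df["mAHP"]) + 0.5
    res = GroupComparison(df, ["mAHP"]).fit()
    assert "mAHP" in res.results
    assert "two_way" in res.results["mAHP"].test
    text = res.summary()
    assert "mAHP" in text and "treatment" in text

    sham = df[df.treatment == "sham"]
    res1 = GroupComparison(sham, ["mAHP"]).fit(design="one_way")
    assert res1.results["mAHP"].test in ("one_way_anova+tukey", "kruskal_wallis+dunn")
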
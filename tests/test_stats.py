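"""Statistical battery against independent textbook oracles.

Every oracle below is implemented from the defining formula, sharing no
code with the package.
"""

import numpy as np
import pytest
from scipy import stats as sps

from qqoef.phantom import make_cohort_roster
from qqoef.roi import apply_exclusions
from qqoef.stats import (distribution_checks, oneway_anova_bonferroni,
                         paired_t_two_tailed, partial_correlation,
                         summarize_cohort)


# ------------------------- oracles -------------------------

def oracle_paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p


def oracle_anova_f(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def oracle_partial_r(x, y, c):
    rxy = np.corrcoef(x, y)[0, 1]
    rxc = np.corrcoef(x, c)[0, 1]
    ryc = np.corrcoef(y, c)[0, 1]
    return (rxy - rxc * ryc) / np.sqrt((1 - rxc ** 2) * (1 - ryc ** 2))


# ------------------------- paired t -------------------------

def test_paired_t_fixture_matches_hand_computation():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([2.0, 2.0, 5.0, 4.0, 7.0])
    res = paired_t_two_tailed(b, a)
    # differences (1,0,2,0,2): mean 1.0, sd 1.0, t = sqrt(5) ~ 2.236, df 4
    assert res.statistic == pytest.approx(np.sqrt(5.0), abs=1e-10)
    assert res.extra["df"] == 4
    t_o, p_o = oracle_paired_t(b, a)
    assert res.statistic == pytest.approx(t_o, abs=1e-10)
    assert res.p == pytest.approx(p_o, abs=1e-10)


def test_paired_t_antisymmetry_and_errors():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 20)
    b = a + 0.5 + rng.normal(0, 0.3, 20)
    r1 = paired_t_two_tailed(a, b)
    r2 = paired_t_two_tailed(b, a)
    assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
    assert r1.p == pytest.approx(r2.p, abs=1e-12)
    with pytest.raises(ValueError):
        paired_t_two_tailed(a, a)
    with pytest.raises(ValueError):
        paired_t_two_tailed(a[:3], b[:4])


# ------------------------- ANOVA + Bonferroni -------------------------

def test_anova_identical_groups_f_zero():
    g = [np.array([1.0, 2.0, 3.0])] * 3
    res = oneway_anova_bonferroni(g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
    res = oneway_anova_bonferroni([a, b])
    t, _ = sps.ttest_ind(a, b)
    assert res.statistic == pytest.approx(t ** 2, abs=1e-10)


def test_anova_four_groups_vs_oracle_and_selective_significance():
    rng = np.random.default_rng(2)
    groups = [rng.normal(0, 1, 25) for _ in range(3)] + [rng.normal(2.0, 1, 25)]
    res = oneway_anova_bonferroni(groups)
    assert res.statistic == pytest.approx(oracle_anova_f(groups), abs=1e-10)
    assert res.p < 0.05
    pw = res.extra["pairwise"]
    for (i, j), d in pw.items():
        t_o, p_o = sps.ttest_ind(groups[i], groups[j])
        assert d["t"] == pytest.approx(t_o, abs=1e-10)
        assert d["p_bonferroni"] == pytest.approx(min(1.0, p_o * 6), abs=1e-10)
        if 3 in (i, j):
            assert d["p_bonferroni"] < 0.05      # only the shifted group differs
        else:
            assert d["p_bonferroni"] > 0.05


def test_bonferroni_dominance_and_p_range():
    rng = np.random.default_rng(3)
    for rep in range(10):
        groups = [rng.normal(rng.normal(0, 0.5), 1, rng.integers(5, 20))
                  for _ in range(4)]
        res = oneway_anova_bonferroni(groups)
        assert 0.0 <= res.p <= 1.0
        for d in res.extra["pairwise"].values():
            assert d["p_bonferroni"] >= d["p_raw"] - 1e-15
            assert 0.0 <= d["p_bonferroni"] <= 1.0


# ------------------------- partial correlation -------------------------

def test_partial_correlation_constant_covariate_is_pearson():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 30)
    y = 0.6 * x + rng.normal(0, 0.5, 30)
    res = partial_correlation(x, y, np.full(30, 2.0))
    assert res.statistic == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


def test_partial_correlation_removes_covariate_effect():
    rng = np.random.default_rng(5)
    c = rng.normal(0, 1, 200)
    x = rng.normal(0, 1, 200)
    y = 3.0 * c                      # y is purely the covariate
    res = partial_correlation(x, y, c)
    assert abs(res.statistic) < 0.1


def test_partial_correlation_six_point_fixture_vs_oracle():
    x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 7.0])
    y = np.array([2.0, 1.0, 3.5, 5.0, 5.5, 8.0])
    c = np.array([0.5, 1.0, 1.5, 2.5, 3.0, 4.0])
    res = partial_correlation(x, y, c)
    assert res.statistic == pytest.approx(oracle_partial_r(x, y, c), abs=1e-12)
    assert res.extra["df"] == 3
    with pytest.raises(ValueError):
        partial_correlation(x[:3], y[:3], c[:3])


# ------------------------- distribution checks -------------------------

def test_ks_normal_sample_usually_passes():
    ok = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        res = distribution_checks(rng.normal(5.0, 2.0, 300))
        ok += res["ks_normality"].p > 0.05
    assert ok >= 90


def test_ks_rejects_uniform_large_sample():
    rng = np.random.default_rng(9)
    res = distribution_checks(rng.uniform(0, 1, 1000))
    assert res["ks_normality"].p < 0.05


def test_levene_identical_groups_statistic_zero():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    res = distribution_checks(np.tile(g, 3), groups=[g, g, g])
    assert res["levene"].statistic == pytest.approx(0.0, abs=1e-12)


# ------------------------- cohort summary -------------------------

@pytest.fixture(scope="module")
def included():
    inc, _ = apply_exclusions(make_cohort_roster(seed=3))
    return inc


def test_summarize_cohort_recovers_designed_means(included):
    summary = summarize_cohort(included)
    tbl = summary.table.set_index("phase")
    designed = {"acute": 0.2604, "early_subacute": 0.2192,
                "late_subacute": 0.2187, "chronic": 0.2158}
    for phase, mean in designed.items():
        assert tbl.loc[phase, "lesion_oef_mean"] == pytest.approx(mean, abs=0.01)
    means = [tbl.loc[p, "lesion_oef_mean"] for p in designed]
    assert means[0] == max(means)           # declining from the acute phase
    assert list(tbl["n"]) == [14, 54, 22, 25]
    assert "lesion_oef" in summary.tests and "nihss" in summary.tests


def test_summarize_cohort_single_phase_no_tests(included):
    one = included[included["phase"] == "acute"]
    summary = summarize_cohort(one)
    assert summary.tests == {}
    assert list(summary.table["n"]) == [14]


def test_summarize_cohort_requires_phase(included):
    with pytest.raises(ValueError):
        summarize_cohort(included.drop(columns=["phase"]))
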
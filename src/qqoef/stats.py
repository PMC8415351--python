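"""Statistical battery and group-summary reporting for ROI metrics.

Thin, contract-checked wrappers over scipy.stats: two-tailed paired t,
one-way ANOVA with Bonferroni-corrected pairwise t tests, partial
correlation (residual method), Kolmogorov-Smirnov normality and Levene
homogeneity checks, plus Kruskal-Wallis / chi-square demographics and a
per-phase summary table.  OEF is formatted as percent with two decimals
and ratios with two decimals at reporting time only; the 0.05
significance threshold is a reporting flag, never a data filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import PHASE_LABELS

__all__ = [
    "TestResult",
    "GroupSummary",
    "paired_t_two_tailed",
    "oneway_anova_bonferroni",
    "partial_correlation",
    "distribution_checks",
    "summarize_cohort",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def paired_t_two_tailed(a, b) -> TestResult:
    """Classical two-tailed paired t test on matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matched 1-D samples")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult("paired t (two-tailed)", float(t), float(p),
                      {"df": len(a) - 1})


def oneway_anova_bonferroni(groups: list) -> TestResult:
    """One-way ANOVA plus Bonferroni-corrected pairwise t tests.

    Pairwise raw p values are multiplied by the number of comparisons and
    capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*groups)
    n_comp = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t_ij, p_ij = sps.ttest_ind(groups[i], groups[j])
            pairwise[(i, j)] = {
                "t": float(t_ij),
                "p_raw": float(p_ij),
                "p_bonferroni": float(min(1.0, p_ij * n_comp)),
            }
    return TestResult("one-way ANOVA", float(f), float(p),
                      {"pairwise": pairwise, "n_comparisons": n_comp})


def partial_correlation(x, y, covariate) -> TestResult:
    """Partial Pearson correlation of x and y controlling one covariate.

    Residual method: the covariate is regressed out of both variables by
    least squares and the residuals are correlated; p comes from the t
    transform with df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(x)
    if not (len(y) == len(c) == n):
        raise ValueError("inputs must have equal length")
    if n < 4:
        raise ValueError("need n >= 4")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    if denom == 0:
        raise ValueError("degenerate residuals")
    r = float(np.sum(rx * ry) / denom)
    df = n - 3
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip ** 2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("partial correlation", r, float(p), {"df": df, "t": float(t)})


def distribution_checks(sample, groups: list | None = None) -> dict[str, TestResult]:
    """Normality (KS vs fitted normal) and, per group set, variance homogeneity.

    The KS test estimates (mean, SD) from the sample, so its p value is
    approximate in the Lilliefors sense; Levene uses the median-centered
    (Brown-Forsythe) variant.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 4:
        raise ValueError("need n >= 4")
    mu, sd = sample.mean(), sample.std(ddof=1)
    ks_stat, ks_p = sps.kstest(sample, "norm", args=(mu, sd))
    out = {"ks_normality": TestResult("Kolmogorov-Smirnov (fitted normal)",
                                      float(ks_stat), float(ks_p))}
    if groups is not None:
        lev_stat, lev_p = sps.levene(*[np.asarray(g, dtype=float) for g in groups],
                                     center="median")
        out["levene"] = TestResult("Levene (Brown-Forsythe)",
                                   float(lev_stat), float(lev_p))
    return out


@dataclass
class GroupSummary:
    """Per-phase summary table with between-group tests."""

    table: pd.DataFrame
    tests: dict[str, TestResult] = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = [self.table.to_markdown(index=False)] if hasattr(
            self.table, "to_markdown") else [self.table.to_string(index=False)]
        for name, t in self.tests.items():
            flag = " *" if t.significant else ""
            lines.append(f"{name}: {t.name} statistic = {t.statistic:.4f}, "
                         f"p = {t.p:.4g}{flag}")
        return "\n".join(lines)


def _fmt_mean_sd(vals: np.ndarray, percent: bool = False) -> str:
    scale = 100.0 if percent else 1.0
    return f"{vals.mean() * scale:.2f} ± {vals.std(ddof=1) * scale:.2f}"


def _fmt_median_iqr(vals: np.ndarray) -> str:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return f"{med:.1f}({q1:.1f}–{q3:.1f})"


def summarize_cohort(records: pd.DataFrame,
                     metric_cols: tuple[str, ...] = ("lesion_oef", "roef"),
                     demographic_cols: tuple[str, ...] = ("nihss", "onset_to_scan_days"),
                     categorical_cols: tuple[str, ...] = ()) -> GroupSummary:
    """Phase-wise summary with the matching between-group tests.

    Continuous demographics are compared across phases with
    Kruskal-Wallis, categorical ones with chi-square, and the OEF-type
    metrics with one-way ANOVA (Bonferroni pairwise).  Single-phase input
    yields the table only.
    """
    if "phase" not in records.columns:
        raise ValueError("records need an assigned 'phase' column")
    phases = [p for p in PHASE_LABELS if p in set(records["phase"])]
    groups = {p: records[records["phase"] == p] for p in phases}

    rows = []
    for p in phases:
        g = groups[p]
        row: dict[str, object] = {"phase": p, "n": len(g)}
        for col in metric_cols:
            vals = g[col].dropna().to_numpy(dtype=float)
            if len(vals):
                row[col] = _fmt_mean_sd(vals, percent=col.endswith("oef") and "r" != col[0])
                row[f"{col}_mean"] = float(vals.mean())
        for col in demographic_cols:
            vals = g[col].dropna().to_numpy(dtype=float)
            if len(vals):
                row[col] = _fmt_median_iqr(vals)
        rows.append(row)
    table = pd.DataFrame(rows)

    tests: dict[str, TestResult] = {}
    if len(phases) >= 2:
        for col in metric_cols:
            samples = [groups[p][col].dropna().to_numpy(dtype=float) for p in phases]
            if all(len(s) >= 2 for s in samples):
                tests[col] = oneway_anova_bonferroni(samples)
        for col in demographic_cols:
            samples = [groups[p][col].dropna().to_numpy(dtype=float) for p in phases]
            if all(len(s) >= 1 for s in samples):
                h, p_kw = sps.kruskal(*samples)
                tests[col] = TestResult("Kruskal-Wallis", float(h), float(p_kw))
        for col in categorical_cols:
            contingency = pd.crosstab(records["phase"], records[col])
            chi2, p_chi, dof, _ = sps.chi2_contingency(contingency)
            tests[col] = TestResult("chi-square", float(chi2), float(p_chi),
                                    {"dof": int(dof)})
    return GroupSummary(table=table, tests=tests)
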
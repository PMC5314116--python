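"""Group statistics: summary-form ANOVA, covariate-adjusted group tests,
pairwise post-hocs, Kruskal-Wallis, brain-behavior regression and BH-FDR.

``anova_from_summary`` reconstructs the one-way fixed-effects F from printed
group means, SDs and sizes, so published demographic tables can be re-analyzed
without raw data. The covariate-adjusted model tests the group factor by the
extra-sum-of-squares F of group indicators over a covariates-only linear
model, matching the "added factors in the model" correction for medication and
comorbidity. SDs are sample (n-1) standard deviations throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class StatsInputError(ValueError):
    pass


@dataclass(frozen=True)
class GroupMoments:
    label: str
    mean: float
    sd: float
    n: int


@dataclass
class GroupSummary:
    """Per-group (mean, SD, n) moments of one variable."""

    variable: str
    groups: list[GroupMoments]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise StatsInputError("need at least two groups")
        for g in self.groups:
            if g.sd < 0:
                raise StatsInputError(f"group {g.label}: negative SD")
            if g.n < 2:
                raise StatsInputError(f"group {g.label}: n must be >= 2")


@dataclass
class TestResult:
    """A single test: statistic, degrees of freedom, raw and adjusted p."""

    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_p: float | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise StatsInputError("p_value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise StatsInputError("adjusted p below raw p")


def anova_from_summary(summary: GroupSummary) -> TestResult:
    """One-way fixed-effects F from group means/SDs/ns.

    MSB = sum n_g (m_g - grand_mean)^2 / (G - 1),
    MSW = sum (n_g - 1) s_g^2 / (N - G), F = MSB / MSW.
    """
    ns = np.array([g.n for g in summary.groups], float)
    means = np.array([g.mean for g in summary.groups], float)
    sds = np.array([g.sd for g in summary.groups], float)
    big_n = ns.sum()
    n_groups = len(ns)
    grand = float(np.dot(ns, means) / big_n)
    msb = float(np.dot(ns, (means - grand) ** 2) / (n_groups - 1))
    msw = float(np.dot(ns - 1, sds**2) / (big_n - n_groups))
    df = (n_groups - 1, big_n - n_groups)
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else math.inf
        p = 1.0 if msb == 0.0 else 0.0
        return TestResult("anova_from_summary", f, df, p, extra={"infinite_f": msb > 0})
    f = msb / msw
    p = float(sps.f.sf(f, *df))
    return TestResult("anova_from_summary", f, df, p)


def summary_from_values(variable: str, values: Sequence[float],
                        groups: Sequence[str]) -> GroupSummary:
    """GroupSummary (sample SDs) computed from raw per-subject values."""
    df = pd.DataFrame({"value": values, "group": groups})
    moments = [
        GroupMoments(str(label), float(sub.mean()), float(sub.std(ddof=1)), int(sub.size))
        for label, sub in df.groupby("group", sort=True)["value"]
    ]
    return GroupSummary(variable, moments)


def adjusted_group_model(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> dict[str, TestResult]:
    """Linear model of value ~ group + covariates; extra-sum-of-squares F tests.

    Group enters as indicator contrasts; binary covariates (medication use,
    comorbid diagnoses) as additional columns. The group effect is the F of
    the full model against the covariates-only model; each covariate is tested
    the same way against the model without it.
    """
    y = np.asarray(values, float)
    gser = pd.Series(groups, dtype="object")
    gdum = pd.get_dummies(gser, prefix="group", drop_first=True, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(y)))
    cov = covariates.reset_index(drop=True).astype(float)
    full_x = sm.add_constant(pd.concat([gdum.reset_index(drop=True), cov], axis=1))
    if np.linalg.matrix_rank(full_x.to_numpy()) < full_x.shape[1]:
        corr = np.corrcoef(full_x.to_numpy()[:, 1:], rowvar=False)
        aliased = [c for i, c in enumerate(full_x.columns[1:])
                   if np.any(np.abs(corr[i, :i]) > 1 - 1e-10)]
        raise StatsInputError(f"rank-deficient design; aliased columns: {aliased}")
    full = sm.OLS(y, full_x).fit()

    def drop_test(cols: list[str], name: str) -> TestResult:
        reduced_x = full_x.drop(columns=cols)
        reduced = sm.OLS(y, reduced_x).fit()
        df1 = len(cols)
        df2 = full.df_resid
        num = (reduced.ssr - full.ssr) / df1
        den = full.ssr / df2
        f = float(num / den)
        p = float(sps.f.sf(f, df1, df2))
        return TestResult(f"adjusted_model[{name}]", f, (df1, df2), p)

    out = {"group": drop_test(list(gdum.columns), "group")}
    for c in cov.columns:
        out[str(c)] = drop_test([c], str(c))
    return out


def pairwise_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    method: str = "bonferroni_welch",
) -> list[TestResult]:
    """All pairwise Welch t tests with Bonferroni or Dunnett-T3 adjustment.

    Dunnett's T3 uses the studentized-maximum-modulus reference with Welch
    degrees of freedom, here approximated (under independence of the pairwise
    statistics) as 1 - (1 - p)^m with the Welch-df t distribution.
    """
    if method not in ("bonferroni_welch", "dunnett_t3"):
        raise StatsInputError(f"unknown post-hoc method {method!r}")
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    by = {str(k): v.to_numpy() for k, v in df.groupby("group", sort=True)["value"]}
    labels = sorted(by)
    for lab in labels:
        if by[lab].size < 2:
            raise StatsInputError(f"group {lab}: needs n >= 2")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    m = len(pairs)
    results = []
    for a, b in pairs:
        t = sps.ttest_ind(by[a], by[b], equal_var=False)
        dof = float(t.df)
        p_raw = float(t.pvalue)
        if method == "bonferroni_welch":
            p_adj = min(1.0, m * p_raw)
        else:
            p_adj = float(1.0 - (1.0 - p_raw) ** m)
        results.append(TestResult(
            f"{method}[{a} vs {b}]", float(t.statistic), (dof,), p_raw,
            adjusted_p=max(p_adj, p_raw),
        ))
    return results


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square p (G-1 df)."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    samples = [v.to_numpy() for _, v in df.groupby("group", sort=True)["value"]]
    if len(samples) < 2:
        raise StatsInputError("need at least two groups")
    if np.ptp(np.concatenate(samples)) == 0:  # all values identical
        return TestResult("kruskal_wallis", 0.0, (float(len(samples) - 1),), 1.0)
    h, p = sps.kruskal(*samples)
    return TestResult("kruskal_wallis", float(h), (float(len(samples) - 1),), float(p))


def brain_behavior_regression(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """OLS slope of connection strength on behavior with Pearson r and slope t test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise StatsInputError("paired observations with n >= 3 required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsInputError("non-finite observations")
    if np.ptp(x) == 0:
        raise StatsInputError("zero variance in x: slope undefined")
    fit = sps.linregress(x, y)
    return TestResult(
        "ols_regression", float(fit.slope), (float(x.size - 2),), float(fit.pvalue),
        extra={"r": float(fit.rvalue), "intercept": float(fit.intercept),
               "stderr": float(fit.stderr)},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH-FDR adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsInputError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]
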
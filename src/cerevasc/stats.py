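"""The statistical battery used throughout the aging analyses.

Normality is decided by a 2-of-3 rule over the D'Agostino–Pearson omnibus,
Shapiro–Wilk, and Lilliefors (Kolmogorov–Smirnov with estimated
parameters) tests at alpha = 0.05.  Group comparisons use classical
one-way ANOVA with Tukey's HSD post hoc (Tukey–Kramer under unequal n),
balanced two-way ANOVA for factorial layouts, and the pooled-variance
(Student) unpaired two-tailed t-test.  P-values map to the significance
stars * / ** / *** / **** at strict thresholds 0.05 / 0.01 / 0.001 /
0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupTable",
    "TestResult",
    "NormalityVerdict",
    "normality_battery",
    "one_way_anova",
    "tukey_hsd",
    "two_way_anova",
    "unpaired_t",
    "star_annotation",
]


def star_annotation(p: float) -> str:
    """Significance stars at strict thresholds; p = 0.05 exactly gets none."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p: float
    name: str = ""
    flags: tuple[str, ...] = ()

    @property
    def stars(self) -> str:
        return star_annotation(self.p)


@dataclass
class GroupTable:
    """Numeric observations with group labels and an optional second factor."""

    values: np.ndarray
    groups: np.ndarray
    factor2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape or self.values.ndim != 1:
            raise ValueError("values and groups must be matched 1D arrays")
        if self.factor2 is not None:
            self.factor2 = np.asarray(self.factor2)
            if self.factor2.shape != self.values.shape:
                raise ValueError("factor2 must match values")

    @classmethod
    def from_dict(cls, data: dict[str, "np.typing.ArrayLike"]) -> "GroupTable":
        values, groups = [], []
        for g, v in data.items():
            v = np.asarray(v, dtype=float)
            values.append(v)
            groups.append(np.full(v.shape, g, dtype=object))
        return cls(np.concatenate(values), np.concatenate(groups))

    def by_group(self) -> dict[str, np.ndarray]:
        return {g: self.values[self.groups == g] for g in pd.unique(self.groups)}


@dataclass(frozen=True)
class NormalityVerdict:
    p_values: dict[str, float]
    passes: dict[str, bool]
    normal: bool
    n_tests: int = field(default=3)


def normality_battery(x, alpha: float = 0.05) -> NormalityVerdict:
    """Three normality tests with a 2-of-3 decision rule.

    For n < 8 the D'Agostino–Pearson omnibus is not applicable; the battery
    degrades to the remaining tests and requires a majority of those, which
    is flagged through ``n_tests``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(x, x[0]):
        raise ValueError("constant sample; normality is undefined")
    p_values: dict[str, float] = {}
    if x.size >= 8:
        p_values["dagostino_pearson"] = float(sps.normaltest(x).pvalue)
    p_values["shapiro_wilk"] = float(sps.shapiro(x).pvalue)
    p_values["lilliefors"] = float(lilliefors(x, dist="norm")[1])
    passes = {k: p > alpha for k, p in p_values.items()}
    needed = 2 if len(p_values) == 3 else (len(p_values) + 1) // 2
    return NormalityVerdict(
        p_values=p_values,
        passes=passes,
        normal=sum(passes.values()) >= needed,
        n_tests=len(p_values),
    )


def one_way_anova(table: GroupTable) -> TestResult:
    """Classical F = MS_between / MS_within with df (k-1, N-k)."""
    groups = table.by_group()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two observations")
    k = len(groups)
    n_total = table.values.size
    grand = table.values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    flags: tuple[str, ...] = ()
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, (df_b, df_w), 1.0, "one_way_anova", ("degenerate",))
        flags = ("zero_within_group_variance",)
        return TestResult(np.inf, (df_b, df_w), 0.0, "one_way_anova", flags)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), (df_b, df_w), p, "one_way_anova", flags)


def tukey_hsd(table: GroupTable) -> dict[tuple[str, str], TestResult]:
    """Tukey's HSD adjusted pairwise comparisons (Tukey–Kramer for unequal n)."""
    groups = table.by_group()
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.tukey_hsd(*[groups[g] for g in names])
    n_total = sum(v.size for v in groups.values())
    df_w = n_total - len(names)
    out: dict[tuple[str, str], TestResult] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            p = res.pvalue[i, j]
            stat = res.statistic[i, j]
            flags: tuple[str, ...] = ()
            if not np.isfinite(p):  # zero within-group variance
                p, flags = 1.0, ("degenerate",)
            out[(a, b)] = TestResult(
                statistic=float(stat) if np.isfinite(stat) else 0.0,
                df=(float(len(names)), float(df_w)),
                p=float(min(p, 1.0)),
                name="tukey_hsd",
                flags=flags,
            )
    return out


def two_way_anova(table: GroupTable) -> dict[str, TestResult]:
    """Balanced two-way ANOVA: main effects (and interaction when replicated).

    Restricted to complete, balanced factorial layouts, where Type-I sums
    of squares are unambiguous; unbalanced input is rejected.
    """
    if table.factor2 is None:
        raise ValueError("two-way ANOVA needs a second factor")
    df = pd.DataFrame(
        {"y": table.values, "A": table.groups.astype(str), "B": table.factor2.astype(str)}
    )
    counts = df.groupby(["A", "B"]).size()
    expected = len(df["A"].unique()) * len(df["B"].unique())
    if len(counts) != expected or counts.nunique() != 1:
        raise ValueError("two-way ANOVA requires a complete, balanced design")
    replicated = counts.iloc[0] > 1
    formula = "y ~ C(A) + C(B)" + (" + C(A):C(B)" if replicated else "")
    model = ols(formula, data=df).fit()
    tab = anova_lm(model, typ=1)
    out: dict[str, TestResult] = {}
    mapping = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    df_resid = float(tab.loc["Residual", "df"])
    for row, key in mapping.items():
        if row in tab.index:
            out[key] = TestResult(
                statistic=float(tab.loc[row, "F"]),
                df=(float(tab.loc[row, "df"]), df_resid),
                p=float(tab.loc[row, "PR(>F)"]),
                name="two_way_anova",
            )
    return out


def unpaired_t(x, y) -> TestResult:
    """Pooled-variance (Student) unpaired two-tailed t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    flags: tuple[str, ...] = ()
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if pooled == 0:
        flags = ("zero_pooled_variance",)
    with warnings.catch_warnings():
        if flags:
            warnings.simplefilter("ignore")
        res = sps.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    return TestResult(float(res.statistic), (float(df),), float(res.pvalue), "unpaired_t", flags)
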
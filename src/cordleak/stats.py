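"""Case aggregation, outlier exclusion, and the cohort comparison tests.

Sections are averaged to one value per case and level before testing. The
single-outlier rule is a one-pass two-sided Grubbs test (alpha 0.2 by
convention here), applied once to the control cohort and propagated as a
persistent per-case exclusion. Comparisons: Mann-Whitney (exact enumeration
for small samples without ties), Welch's t, Pearson/least-squares regression,
and two-way ANOVA (Type III sums of squares, sum-to-zero coding) with Sidak
or Tukey post-tests; a repeated-measures variant treats both factors as
within-subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "CaseLevelValue",
    "TestResult",
    "aggregate_case",
    "grubbs_outlier",
    "mann_whitney",
    "welch_t",
    "pearson_linreg",
    "two_way_anova",
    "tukey_levels",
    "sidak_adjust",
]


@dataclass
class CaseLevelValue:
    """Mean of a case's sections at one level."""

    case: str
    group: str
    level: str
    value: float
    n_sections: int


@dataclass
class TestResult:
    """Uniform container for a statistical comparison."""

    name: str
    statistic: float
    pvalue: float
    method: str = ""
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def aggregate_case(section_values, case: str = "", group: str = "",
                   level: str = "") -> CaseLevelValue:
    """Arithmetic mean of the available section values (order-invariant)."""
    vals = np.asarray(list(section_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no section values to aggregate")
    return CaseLevelValue(case, group, level, float(vals.mean()), int(vals.size))


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t quantile."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values, alpha: float = 0.2) -> int | None:
    """One-pass two-sided single-outlier Grubbs test.

    Returns the index of the single most extreme value when its studentized
    deviation G = max|x - mean| / sd exceeds the critical value, else
    ``None``. Ties in |deviation| go to the first index. Never iterates.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    return idx if g > grubbs_critical(x.size, alpha) else None


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the smaller sample has at most 8 values and there
    are no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = min(a.size, b.size) <= 8 and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    direction = "a>b" if np.median(a) > np.median(b) else "a<b"
    return TestResult("Mann-Whitney", float(res.statistic), float(res.pvalue),
                      method="exact" if exact else "normal approximation",
                      extra={"direction": direction})


def welch_t(a, b) -> TestResult:
    """Two-sided Welch's t (Welch-Satterthwaite degrees of freedom)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t needs at least 2 values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("Welch t", float(res.statistic), float(res.pvalue),
                      method="Welch-Satterthwaite",
                      extra={"df": float(res.df),
                             "direction": "a>b" if a.mean() > b.mean() else "a<b"})


def pearson_linreg(x, y) -> TestResult:
    """Pearson correlation with the least-squares line through (x, y)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    lr = sps.linregress(x, y)
    return TestResult("Pearson/linreg", float(lr.rvalue), float(lr.pvalue),
                      method="least squares",
                      extra={"slope": float(lr.slope),
                             "intercept": float(lr.intercept),
                             "r": float(lr.rvalue)})


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family adjustment 1 - (1 - p)^m (identity at m = 1)."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0,1] and m >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def _pooled_mse(df: pd.DataFrame) -> tuple[float, int]:
    """Residual mean square and df from the full group x level cell model."""
    resid_ss, resid_df = 0.0, 0
    for _, cell in df.groupby(["group", "level"], observed=True):
        v = cell["value"].to_numpy()
        if v.size > 1:
            resid_ss += float(((v - v.mean()) ** 2).sum())
            resid_df += v.size - 1
    if resid_df == 0:
        raise ValueError("no residual degrees of freedom")
    return resid_ss / resid_df, resid_df


def _sidak_posthoc(df: pd.DataFrame, mse: float, dfe: int) -> pd.DataFrame:
    """Between-group comparison at each level, Sidak-adjusted over levels."""
    levels = list(df["level"].unique())
    groups = list(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("Sidak between-group post-test expects 2 groups")
    m = len(levels)
    rows = []
    for lev in levels:
        g1 = df.loc[(df["level"] == lev) & (df["group"] == groups[0]), "value"].to_numpy()
        g2 = df.loc[(df["level"] == lev) & (df["group"] == groups[1]), "value"].to_numpy()
        se = np.sqrt(mse * (1.0 / g1.size + 1.0 / g2.size))
        t = (g1.mean() - g2.mean()) / se
        p = 2.0 * sps.t.sf(abs(t), dfe)
        rows.append({"comparison": f"{groups[0]} vs {groups[1]} @ {lev}",
                     "level": lev, "t": float(t), "p_raw": float(p),
                     "p_adj": sidak_adjust(p, m)})
    return pd.DataFrame(rows)


def _tukey_posthoc(df: pd.DataFrame, mse: float, dfe: int,
                   within: str = "group") -> pd.DataFrame:
    """Tukey-Kramer comparisons across levels within each group."""
    rows = []
    for grp, sub in df.groupby(within, observed=True):
        levels = list(sub["level"].unique())
        k = len(levels)
        for i in range(k):
            for j in range(i + 1, k):
                a = sub.loc[sub["level"] == levels[i], "value"].to_numpy()
                b = sub.loc[sub["level"] == levels[j], "value"].to_numpy()
                se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(a.mean() - b.mean()) / se
                p = float(sps.studentized_range.sf(q, k, dfe))
                rows.append({"comparison": f"{grp}: {levels[i]} vs {levels[j]}",
                             "group": grp, "q": float(q),
                             "p_adj": min(1.0, p),
                             "direction": f"{levels[i]}>{levels[j]}"
                             if a.mean() > b.mean() else f"{levels[j]}>{levels[i]}"})
    return pd.DataFrame(rows)


def tukey_levels(data: pd.DataFrame) -> pd.DataFrame:
    """Tukey-Kramer comparisons across levels within each group present.

    Accepts a ``group``/``level``/``value`` table with one or more groups;
    the residual mean square is pooled over all cells.
    """
    df = data.copy()
    if "group" not in df:
        df["group"] = "all"
    mse, dfe = _pooled_mse(df)
    return _tukey_posthoc(df, mse, dfe)


def two_way_anova(data: pd.DataFrame, posthoc: str = "sidak",
                  repeated: str = "none") -> TestResult:
    """Two-factor ANOVA over a ``group`` x ``level`` table of case values.

    ``data`` columns: ``group``, ``level``, ``value`` and, for
    ``repeated='both'``, ``subject``. Between-subject designs use Type III
    sums of squares with sum-to-zero coding (robust to the unbalanced
    control/ALS cohort sizes); the repeated-measures variant treats both
    factors as within-subject and requires a complete design.

    Post-tests: ``sidak`` compares the two groups at each level (family =
    number of levels); ``tukey`` compares levels within each group via the
    studentized range.
    """
    if posthoc not in ("sidak", "tukey", "none"):
        raise ValueError("posthoc must be 'sidak', 'tukey' or 'none'")
    df = data.copy()
    if repeated == "both":
        counts = df.groupby(["subject", "group", "level"], observed=True).size()
        n_cells = df["group"].nunique() * df["level"].nunique()
        per_subject = counts.groupby("subject", observed=True).size()
        if (counts != 1).any() or (per_subject != n_cells).any():
            raise ValueError("repeated='both' requires a complete "
                             "within-subject design (one value per cell)")
        rm = AnovaRM(df, depvar="value", subject="subject",
                     within=["group", "level"]).fit()
        tab = rm.anova_table
        stat = float(tab["F Value"].iloc[0])
        p = float(tab["Pr > F"].iloc[0])
        post = None
        if posthoc == "sidak":
            rows = []
            levels = list(df["level"].unique())
            groups = list(df["group"].unique())
            for lev in levels:
                wide = df[df["level"] == lev].pivot(index="subject",
                                                    columns="group",
                                                    values="value")
                t, praw = sps.ttest_rel(wide[groups[0]], wide[groups[1]])
                rows.append({"comparison": f"{groups[0]} vs {groups[1]} @ {lev}",
                             "level": lev, "t": float(t), "p_raw": float(praw),
                             "p_adj": sidak_adjust(float(praw), len(levels))})
            post = pd.DataFrame(rows)
        return TestResult("RM two-way ANOVA", stat, p, method="AnovaRM",
                          posthoc=post, extra={"table": tab})

    if df.groupby(["group", "level"], observed=True).size().min() < 1:
        raise ValueError("empty cell in the between-subject design")
    model = ols("value ~ C(group, Sum) * C(level, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    mse, dfe = _pooled_mse(df)
    stat = float(tab.loc["C(group, Sum)", "F"])
    p = float(tab.loc["C(group, Sum)", "PR(>F)"])
    post = None
    if posthoc == "sidak":
        post = _sidak_posthoc(df, mse, dfe)
    elif posthoc == "tukey":
        post = _tukey_posthoc(df, mse, dfe)
    return TestResult("two-way ANOVA", stat, p, method="Type III / sum coding",
                      posthoc=post, extra={"table": tab, "mse": mse, "dfe": dfe})
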
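"""The cohort comparison battery: aggregation, exclusion, and every table.

``run_paper_battery`` takes the per-section results table and per-case
metadata, averages sections to one value per case and level, applies the
one-pass Grubbs exclusion (alpha 0.2) to the control cohort on the requested
variables — an excluded case is dropped from *every* subsequent table — and
then produces, per variable:

* within-group comparisons across segmental levels (Tukey across the three
  levels, pooled residual mean square);
* between-group comparison at each level (two-way ANOVA, Sidak family over
  the levels);
* the pooled control-vs-ALS Welch t test on case means.

Tables are returned in a deterministic order keyed ``variable/table``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import grubbs_outlier, tukey_levels, two_way_anova, welch_t

__all__ = ["BatteryReport", "aggregate_results", "apply_grubbs_exclusion",
           "run_paper_battery"]

DEFAULT_VARIABLES = ("gm_hb_intensity_per_mm2", "wm_hb_intensity_per_mm2",
                     "gm_vessel_density", "wm_vessel_density")


@dataclass
class BatteryReport:
    """All comparison tables plus the exclusion bookkeeping."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_cases: list[str] = field(default_factory=list)
    group_n: dict[str, int] = field(default_factory=dict)

    def to_frames(self) -> pd.DataFrame:
        """All tables concatenated with a ``table`` key column."""
        out = []
        for key, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "table", key)
            out.append(t)
        return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def aggregate_results(results: pd.DataFrame, metadata: pd.DataFrame,
                      variable: str) -> pd.DataFrame:
    """Section rows -> one mean per case and level, with group attached."""
    agg = (results.groupby(["case", "level"], observed=True)[variable]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "value", "size": "n_sections"}))
    meta = metadata[["case", "group"]].drop_duplicates("case")
    out = agg.merge(meta, on="case", how="left")
    missing = out["group"].isna()
    if missing.any():
        raise ValueError(f"cases without metadata: {sorted(out.loc[missing, 'case'])}")
    return out


def apply_grubbs_exclusion(case_values: pd.DataFrame, alpha: float = 0.2,
                           group: str = "control") -> list[str]:
    """Identify at most one outlying case within ``group`` (Grubbs, one pass).

    The test runs on the per-case mean over levels of the supplied variable;
    the returned case list is meant to be excluded from every table.
    """
    sub = (case_values[case_values["group"] == group]
           .groupby("case", observed=True)["value"].mean())
    if len(sub) < 3:
        return []
    idx = grubbs_outlier(sub.to_numpy(), alpha=alpha)
    return [str(sub.index[idx])] if idx is not None else []


def run_paper_battery(results: pd.DataFrame, metadata: pd.DataFrame,
                      variables: tuple[str, ...] = DEFAULT_VARIABLES,
                      grubbs_variables: tuple[str, ...] | None = None,
                      grubbs_alpha: float = 0.2,
                      control_group: str = "control") -> BatteryReport:
    """Run every cohort comparison; see the module docstring for the set.

    ``grubbs_variables`` (default: the analysis variables themselves)
    determines which variables the control-cohort outlier screen runs on; a
    case flagged on any of them is excluded everywhere.
    """
    report = BatteryReport()
    variables = tuple(v for v in variables if v in results.columns)

    # --- outlier screen, once, on the control cohort -----------------------
    excluded: set[str] = set()
    has_control = (metadata["group"] == control_group).any()
    if has_control:
        for var in (grubbs_variables or variables):
            if var not in results.columns:
                continue
            cv = aggregate_results(results, metadata, var)
            excluded.update(apply_grubbs_exclusion(cv, grubbs_alpha, control_group))
    report.excluded_cases = sorted(excluded)
    results = results[~results["case"].isin(excluded)]
    metadata = metadata[~metadata["case"].isin(excluded)]
    report.group_n = metadata.drop_duplicates("case")["group"] \
        .value_counts().to_dict()

    groups = sorted(metadata["group"].unique())
    for var in variables:
        cv = aggregate_results(results, metadata, var)
        # within-group level comparisons (Tukey)
        tuk = tukey_levels(cv)
        report.tables[f"{var}/levels_tukey"] = tuk
        # between-group at each level (Sidak) + pooled Welch t
        if len(groups) == 2:
            res = two_way_anova(cv, posthoc="sidak")
            report.tables[f"{var}/group_by_level_sidak"] = res.posthoc
            a = cv.loc[cv["group"] == groups[0]].groupby("case")["value"].mean()
            b = cv.loc[cv["group"] == groups[1]].groupby("case")["value"].mean()
            wt = welch_t(a, b)
            report.tables[f"{var}/pooled_welch"] = pd.DataFrame([{
                "comparison": f"{groups[0]} vs {groups[1]} (pooled)",
                "t": wt.statistic, "p": wt.pvalue,
                "n_a": len(a), "n_b": len(b),
                "direction": wt.extra["direction"]}])
    return report
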
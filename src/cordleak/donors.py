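"""Built-in post-mortem donor demographics table and its summary statistics.

The donor table (5 neurologically normal controls, 13 ALS cases, with age,
sex, post-mortem delay, and for ALS cases the sporadic/familial status and
site of onset) is the worked-example input for the cohort statistics: the
per-group mean and standard deviation of age and post-mortem delay are
recomputed from the printed rows.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["donor_table", "donor_summary"]

_DONOR_CSV = """\
case,group,age_y,sex,pmd_h,als_type,onset_site
H232,control,89,F,28.5,,
H233,control,83,F,18,,
H234,control,86,M,3,,
H235,control,83,M,21,,
H236,control,96,F,15,,
MN7,ALS,55,F,56,sALS,Upper limb
MN10,ALS,46,M,24,sALS,Lower limb
MN11,ALS,77,F,18,fALS,Lower limb
MN12,ALS,49,M,34,sALS,Respiratory
MN13,ALS,55,M,10,sALS,Upper limb
MN14,ALS,59,F,19,fALS,Bulbar
MN15,ALS,54,F,18,sALS,FTD
MN16,ALS,69,M,16.5,sALS,Upper limb
MN18,ALS,53,F,12,fALS (C9ORF72),Lower limb
MN20,ALS,85,M,15,sALS,Lower limb
MN21,ALS,59,F,17.5,fALS,Lower limb
MN22,ALS,64,F,9,sALS,Upper limb
MN23,ALS,79,F,27,fALS (C9ORF72),Lower limb
"""


def donor_table() -> pd.DataFrame:
    """The donor demographics table as a DataFrame (fresh copy)."""
    return pd.read_csv(io.StringIO(_DONOR_CSV))


def donor_summary() -> pd.DataFrame:
    """Per-group mean/SD (ddof=1) of donor age and post-mortem delay,
    plus female/male counts."""
    df = donor_table()
    rows = []
    for group, sub in df.groupby("group", sort=False):
        rows.append({
            "group": group,
            "n": len(sub),
            "age_mean": sub["age_y"].mean(),
            "age_sd": sub["age_y"].std(ddof=1),
            "pmd_mean": sub["pmd_h"].mean(),
            "pmd_sd": sub["pmd_h"].std(ddof=1),
            "n_female": int((sub["sex"] == "F").sum()),
            "n_male": int((sub["sex"] == "M").sum()),
        })
    return pd.DataFrame(rows)
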
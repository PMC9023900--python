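"""Published summary statistics of the COMPAS recidivism cohort.

The 7,214-record COMPAS cohort (two-year recidivism outcome, six binary
predictors) is a standard benchmark for studying variable-importance
claims about race. The raw data are not bundled; what is bundled are the
published per-variable contingency *counts* of the cohort, from which the
descriptive percentages and chi-squared tests are recomputed on the fly.
This gives a fully checkable worked example of simple contingency
arithmetic without any download.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["summary_counts", "summary_table"]

# (variable, level, count among 3,743 non-recidivists, count among 3,471
# recidivists); the overall column is the sum of the two.
_COUNTS = [
    ("age", "18-20 years", 47, 173),
    ("age", ">20 years", 3696, 3298),
    ("gender", "female", 865, 530),
    ("gender", "male", 2878, 2941),
    ("race", "african_american", 1660, 2036),
    ("race", "others", 2083, 1435),
    ("prior_criminal_history", "yes", 1478, 672),
    ("prior_criminal_history", "no", 2265, 2799),
    ("juvenile_criminal_history", "yes", 3489, 2752),
    ("juvenile_criminal_history", "no", 254, 719),
    ("current_charge", "degree_misdemeanor", 1496, 1052),
    ("current_charge", "others", 2247, 2419),
]


def summary_counts() -> pd.DataFrame:
    """Contingency counts by variable level and two-year recidivism status."""
    df = pd.DataFrame(
        _COUNTS, columns=["variable", "level", "no_recidivism", "recidivism"]
    )
    df["all"] = df["no_recidivism"] + df["recidivism"]
    return df


def summary_table(decimals: int = 1) -> pd.DataFrame:
    """Counts plus recomputed column percentages and chi-squared p values.

    Percentages are within-column (overall cohort, non-recidivists,
    recidivists), rounded to ``decimals``; the chi-squared test compares
    the level distribution between outcome groups, one test per variable.
    """
    df = summary_counts()
    totals = {c: df.groupby("variable")[c].transform("sum")
              for c in ("all", "no_recidivism", "recidivism")}
    df["pct_all"] = (100 * df["all"] / totals["all"]).round(decimals)
    df["pct_no_recidivism"] = (
        100 * df["no_recidivism"] / totals["no_recidivism"]
    ).round(decimals)
    df["pct_recidivism"] = (
        100 * df["recidivism"] / totals["recidivism"]
    ).round(decimals)
    pvals = {}
    for var, grp in df.groupby("variable"):
        table = grp[["no_recidivism", "recidivism"]].to_numpy()
        pvals[var] = stats.chi2_contingency(table)[1]
    df["chi2_p"] = df["variable"].map(pvals)
    return df
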
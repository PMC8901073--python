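"""Growth-performance and mortality summaries with one-way ANOVA.

Average daily gain (ADG) spans 26 days pre-weaning (day 1 to day 26) and
32 days post-weaning (day 26 to day 58). Mortality is compared between
diet groups by ANOVA on per-animal 0/1 death indicators (denominator the
initial group size); a chi-square test is available as an alternative.
The whole-trial "ADG overall" is not derivable from group-mean weights
when survivor composition changes, so group summaries report it as
missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PRE_DAYS = 26   # day 1 -> day 26 (weaning)
POST_DAYS = 32  # day 26 -> day 58


def adg(bw_start: float, bw_end: float, days: int) -> float:
    """Average daily gain in kg/day over a span of days."""
    if days <= 0:
        raise ValueError(f"days must be positive, got {days}")
    return (bw_end - bw_start) / days


def oneway_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with (k-1, n-k) degrees of freedom.

    Degenerate inputs: zero spread both between and within groups gives
    F = 0, p = 1; zero within-group spread with distinct means gives
    F = inf, p = 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    n = values.size
    k = labels.size
    if n - k < 1:
        raise ValueError("need at least one group with two or more values")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in labels:
        v = values[groups == g]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no values")
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return float(f), float(stats.f.sf(f, k - 1, n - k))


def mortality_chi2(deaths, totals) -> tuple[float, float]:
    """Chi-square test of equal death proportions across groups."""
    deaths = np.asarray(deaths)
    totals = np.asarray(totals)
    table = np.column_stack([deaths, totals - deaths])
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)


def group_summary(records: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Per-group growth and mortality summary with ANOVA p-values.

    ``records`` has one row per piglet with columns pig, group, bw_d1,
    bw_d26, bw_d58, alive_pre, alive_post. Means are over animals alive at
    the weighing day; ADG is averaged per animal; mortality proportions
    use the initial group size. The p-value series is ``None`` when only
    one group is present.
    """
    df = records.copy()
    df["adg_pre"] = (df["bw_d26"] - df["bw_d1"]) / PRE_DAYS
    df["adg_post"] = (df["bw_d58"] - df["bw_d26"]) / POST_DAYS
    df["died_pre"] = (~df["alive_pre"]).astype(float)
    df["died_post"] = (df["alive_pre"] & ~df["alive_post"]).astype(float)

    rows = {}
    for g, sub in df.groupby("group", sort=False):
        rows[g] = {
            "n": len(sub),
            "bw_d1": sub["bw_d1"].mean(),
            "bw_d26": sub["bw_d26"].mean(),
            "bw_d58": sub["bw_d58"].mean(),
            "adg_pre": sub["adg_pre"].mean(),
            "adg_post": sub["adg_post"].mean(),
            "adg_overall": np.nan,
            "mortality_pre": sub["died_pre"].mean(),
            "mortality_post": sub["died_post"].mean(),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "group"
    if df["group"].nunique() < 2:
        return summary, None

    pvals = {}
    for col in ("bw_d1", "bw_d26", "bw_d58", "adg_pre", "adg_post",
                "died_pre", "died_post"):
        mask = df[col].notna()
        if df.loc[mask, "group"].nunique() < 2:
            pvals[col] = np.nan
            continue
        _, p = oneway_anova(df.loc[mask, col], df.loc[mask, "group"])
        pvals[col] = p
    pvals = pd.Series(pvals).rename(
        index={"died_pre": "mortality_pre", "died_post": "mortality_post"})
    return summary, pvals
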
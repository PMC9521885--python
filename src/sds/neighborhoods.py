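"""Neighborhood disparity analysis on zip-level sensitivity scores.

Quartile classification of zips by mean SDS, one-way ANOVA with Tukey HSD
post-hoc comparison of covariates across the four sensitivity groups,
Pearson correlation of SDS with health indicators, and the police-action
disparity test: within each sensitivity quartile, a Welch two-sample t-test
of a demographic share between zips with low (< 0.3) and high (> 0.6)
police-action-taken rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

QUARTILE_LABELS = ["low", "medium-low", "medium-high", "high"]


@dataclass
class QuartileGrouping:
    labels: pd.Series           # zip -> quartile label
    cut_points: tuple[float, float, float]
    group_means: pd.Series      # label -> mean SDS_z

    def group(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class PoliceActionComparison:
    rows: pd.DataFrame          # one row per quartile
    low: float
    high: float


def classify_quartiles(zip_scores: pd.DataFrame) -> QuartileGrouping:
    """Assign each zip a sensitivity quartile label.

    Cut points are the empirical 25th/50th/75th percentiles of SDS_z (linear
    interpolation between closest ranks). Bins are "low" for SDS <= Q1 and
    then half-open upward, so a zip tied exactly with a cut point lands in
    the lower group.
    """
    if len(zip_scores) < 4:
        raise ValueError("quartile classification needs at least 4 zips")
    s = zip_scores.set_index("zip")["SDS_z"].astype(float)
    q1, q2, q3 = np.percentile(s.to_numpy(), [25, 50, 75])
    if q1 == q3:
        raise ValueError("degenerate SDS distribution: quartile cut points coincide")
    labels = pd.Series(
        np.select(
            [s <= q1, s <= q2, s <= q3],
            QUARTILE_LABELS[:3],
            default=QUARTILE_LABELS[3],
        ),
        index=s.index,
        name="quartile",
    )
    means = s.groupby(labels).mean().reindex(QUARTILE_LABELS)
    return QuartileGrouping(labels=labels, cut_points=(q1, q2, q3), group_means=means)


def compare_groups(
    grouping: QuartileGrouping, covariate_table: pd.DataFrame, posthoc: bool = True
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD of each covariate across quartile groups.

    Missing covariate values are dropped pairwise, with the per-covariate n
    reported. A covariate constant within every group gets a flagged row
    (F = 0, p = 1) instead of a crash. Returns a long table: one summary row
    per covariate plus one row per Tukey pair.
    """
    cov = covariate_table.set_index("zip")
    labels = grouping.labels
    rows = []
    for name in cov.columns:
        x = cov[name].astype(float)
        df = pd.DataFrame({"value": x, "group": labels}).dropna()
        groups = [g["value"].to_numpy() for _, g in df.groupby("group")]
        groups = [g for g in groups if len(g) >= 2]
        summary = {
            "covariate": name,
            "kind": "anova",
            "n": int(len(df)),
        }
        for lab in QUARTILE_LABELS:
            sel = df[df["group"] == lab]["value"]
            summary[f"mean_{lab}"] = sel.mean() if len(sel) else np.nan
            summary[f"sd_{lab}"] = sel.std(ddof=1) if len(sel) > 1 else np.nan
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups) and len(
            {g[0] for g in groups}
        ) == 1:
            summary.update({"F": 0.0, "p": 1.0, "flag": "constant-or-degenerate"})
            rows.append(summary)
            continue
        F, p = stats.f_oneway(*groups)
        if np.isnan(F):
            summary.update({"F": 0.0, "p": 1.0, "flag": "constant-or-degenerate"})
            rows.append(summary)
            continue
        summary.update({"F": float(F), "p": float(p), "flag": ""})
        rows.append(summary)
        if not posthoc:
            continue
        tuk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
        pairs = [
            (tuk.groupsunique[i], tuk.groupsunique[j])
            for i in range(len(tuk.groupsunique))
            for j in range(i + 1, len(tuk.groupsunique))
        ]
        for (g1, g2), md, padj, rej in zip(
            pairs, tuk.meandiffs, tuk.pvalues, tuk.reject
        ):
            rows.append(
                {
                    "covariate": name,
                    "kind": "tukey",
                    "pair": f"{g1} vs {g2}",
                    "meandiff": float(md),
                    "p": float(padj),
                    "reject": bool(rej),
                }
            )
    return pd.DataFrame(rows)


def correlate_indicators(
    zip_scores: pd.DataFrame,
    covariate_table: pd.DataFrame,
    indicators: list[str],
) -> pd.DataFrame:
    """Pearson correlation of SDS_z with each named health indicator."""
    merged = zip_scores.merge(covariate_table, on="zip", how="inner")
    rows = []
    for name in indicators:
        if name not in merged.columns:
            raise ValueError(f"indicator {name!r} not in covariate table")
        df = merged[["SDS_z", name]].dropna()
        if len(df) < 3:
            raise ValueError(f"indicator {name!r}: need >= 3 paired observations")
        x, y = df["SDS_z"].to_numpy(), df[name].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"indicator": name, "r": np.nan, "p": np.nan,
                         "n": len(df), "flag": "zero-variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"indicator": name, "r": float(r), "p": float(p),
                     "n": len(df), "flag": ""})
    return pd.DataFrame(rows)


def police_action_rates(
    complaint_table: pd.DataFrame, unit_table: pd.DataFrame
) -> pd.Series:
    """Per-zip fraction of complaints with a police action flag.

    Complaints are attributed to zips through their unit's zip; zips with
    zero complaints are omitted (a rate of 0/0 is undefined, not 0).
    """
    c = complaint_table.merge(
        unit_table[["unit_id", "zip"]],
        left_on="building_id",
        right_on="unit_id",
        how="inner",
    )
    if "police_action" not in c.columns:
        raise ValueError("complaint table lacks a police_action column")
    g = c.groupby("zip")["police_action"]
    return (g.sum() / g.count()).rename("police_action_rate")


def compare_police_by_group(
    rates: pd.Series,
    grouping: QuartileGrouping,
    covariate_table: pd.DataFrame,
    demographic_col: str = "nh_white_share",
    low: float = 0.3,
    high: float = 0.6,
) -> PoliceActionComparison:
    """Demographic composition of low- vs high-police-response zips, within
    each sensitivity quartile.

    Zips with action rate < ``low`` form one stratum, > ``high`` the other;
    zips in between are excluded. A Welch t-test compares the demographic
    share between strata. Quartiles where either stratum has fewer than two
    zips are flagged and skipped.
    """
    if not (0.0 < low < high < 1.0):
        raise ValueError("thresholds must satisfy 0 < low < high < 1")
    cov = covariate_table.set_index("zip")
    if demographic_col not in cov.columns:
        raise ValueError(f"covariate table lacks {demographic_col!r}")
    rows = []
    for lab in QUARTILE_LABELS:
        zips = [z for z in grouping.group(lab) if z in rates.index]
        r = rates.loc[zips]
        lo_z = [z for z in zips if r[z] < low]
        hi_z = [z for z in zips if r[z] > high]
        row = {
            "quartile": lab,
            "n_low": len(lo_z),
            "n_high": len(hi_z),
            "share_low": cov.loc[lo_z, demographic_col].mean() if lo_z else np.nan,
            "share_high": cov.loc[hi_z, demographic_col].mean() if hi_z else np.nan,
        }
        if len(lo_z) < 2 or len(hi_z) < 2:
            row.update({"t": np.nan, "p": np.nan, "flag": "stratum-too-small"})
        else:
            t, p = stats.ttest_ind(
                cov.loc[lo_z, demographic_col].dropna(),
                cov.loc[hi_z, demographic_col].dropna(),
                equal_var=False,
            )
            row.update({"t": float(t), "p": float(p), "flag": ""})
        rows.append(row)
    return PoliceActionComparison(rows=pd.DataFrame(rows), low=low, high=high)
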
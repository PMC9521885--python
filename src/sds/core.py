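"""Per-unit sensitivity thresholds and the SDS score.

The psychophysical model: crowding at an establishment is the stimulus,
a complaint is the response. For each scoring unit,

* the absolute threshold ``A`` is the mean activity intensity (visits per
  10,000 sq ft per six-hour interval) over open intervals in which a
  complaint was reported — the average stimulus that provoked a response;
* the difference threshold ``D`` (Weber fraction) is the fractional excess
  of ``A`` over the unit's baseline mean intensity (open, complaint-free
  intervals) — the just-noticeable relative increase in crowding;
* the subjective sensation follows Fechner's law, ``SS = D x log(A)``;
* the SDS score is the inverse min-max rescaling of SS over all scored
  units, times 100, so the most tolerant unit (largest SS) scores 0 and the
  most sensitive (smallest SS) scores 100.

SDS is invariant to the log base (the min-max normalization absorbs the
positive constant relating two bases) but NOT to the intensity unit, because
``log A`` shifts additively while ``D`` multiplies: intensities are pinned
to visits per 10,000 sq ft.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from sds.config import ScoreConfig
from sds.ingest import FilterLedger


def activity_intensity(visits: float, floor_area: float, scale: float = 10_000.0) -> float:
    """Visits per `scale` square feet of floor area."""
    if floor_area <= 0:
        raise ValueError("floor_area must be > 0")
    return visits * scale / floor_area


def absolute_threshold(complaint_intensities: Sequence[float]) -> float:
    """Mean intensity over complaint-flagged open intervals."""
    xs = list(complaint_intensities)
    if not xs:
        raise ValueError("no complaint intervals: unit cannot be scored")
    return float(sum(xs)) / len(xs)


def difference_threshold(A: float, baseline_intensities: Sequence[float]) -> float:
    """Weber fraction: (A - baseline mean) / baseline mean.

    Negative values (complaint-time density below baseline) are kept as
    computed; flooring them would silently distort the min-max range.
    """
    xs = list(baseline_intensities)
    if not xs:
        raise ValueError("no baseline intervals: unit cannot be scored")
    m = float(sum(xs)) / len(xs)
    if m <= 0:
        raise ValueError("baseline mean must be > 0 to form a Weber fraction")
    return (A - m) / m


def subjective_sensation(D: float, A: float, log_base: float = 10.0) -> float:
    """Fechner's law: SS = D x log_base(A)."""
    if A <= 0:
        raise ValueError("absolute threshold must be > 0")
    return D * math.log(A, log_base)


def sds_scores(ss_values: Sequence[float]) -> np.ndarray:
    """Inverse min-max rescaling of sensation values to a 0-100 score.

    The unit with maximal SS (most tolerant) gets 0, minimal SS gets 100;
    ties at either extreme share the endpoint. Requires at least two units
    with distinct SS — otherwise the normalization is undefined.
    """
    ss = np.asarray(list(ss_values), dtype=float)
    if ss.size < 2:
        raise ValueError(
            "SDS normalization needs >= 2 scored units; score more units or "
            "lower min_baseline"
        )
    lo, hi = ss.min(), ss.max()
    if hi == lo:
        raise ValueError(
            "all subjective sensation values are equal: min-max normalization "
            "is undefined (degenerate city)"
        )
    return np.abs(1.0 - (ss - lo) / (hi - lo)) * 100.0


def score_units(
    interval_table: pd.DataFrame,
    unit_table: pd.DataFrame,
    config: ScoreConfig | None = None,
    ledger: FilterLedger | None = None,
) -> tuple[pd.DataFrame, FilterLedger]:
    """Estimate A, D, SS and SDS for every scoreable unit.

    A unit is scoreable when it has at least one open complaint interval with
    positive visits and at least ``config.min_baseline`` open complaint-free
    intervals with positive baseline mean. Closed intervals never count;
    complaint intervals with zero recorded visits are routed to the ledger
    rather than diluting A. Units failing the requirements are excluded with
    a ledger entry, mirroring the study design of scoring only units that
    received at least one complaint.
    """
    config = config or ScoreConfig()
    ledger = ledger or FilterLedger()

    t = interval_table
    if "intensity" not in t.columns:
        areas = unit_table.set_index("unit_id")["floor_area"]
        t = t.assign(intensity=t["visits"] * config.intensity_scale / t["unit_id"].map(areas))

    open_t = t[t["open"]]
    ledger.record("scoring: open intervals only", len(t), len(open_t))
    comp = open_t[open_t["complaint"]]
    comp_pos = comp[comp["visits"] > 0]
    ledger.record("scoring: complaint intervals with recorded visits", len(comp), len(comp_pos))
    base = open_t[~open_t["complaint"]]

    if config.stratify_baseline:
        # Time-of-day-matched baseline: weight each slot's baseline mean by
        # the unit's complaint-slot frequencies.
        comp_pos = comp_pos.assign(slot=comp_pos["interval_start"].dt.hour)
        base = base.assign(slot=base["interval_start"].dt.hour)

    rows = []
    log_b = math.log(config.log_base)
    comp_g = comp_pos.groupby("unit_id")
    base_g = base.groupby("unit_id")
    base_stats = base_g["intensity"].agg(["mean", "count"])
    if config.stratify_baseline:
        slot_means = base.groupby(["unit_id", "slot"])["intensity"].mean()

    for unit_id, grp in comp_g:
        if unit_id not in base_stats.index:
            continue
        n_base = int(base_stats.loc[unit_id, "count"])
        if n_base < config.min_baseline:
            continue
        A = float(grp["intensity"].mean())
        if config.stratify_baseline:
            means = [
                slot_means.get((unit_id, s), np.nan) for s in grp["slot"]
            ]
            means = [m for m in means if not np.isnan(m)]
            if not means:
                continue
            base_mean = float(np.mean(means))
        else:
            base_mean = float(base_stats.loc[unit_id, "mean"])
        if base_mean <= 0 or A <= 0:
            continue
        rows.append(
            {
                "unit_id": unit_id,
                "A": A,
                "D": (A - base_mean) / base_mean,
                "SS": (A - base_mean) / base_mean * math.log(A) / log_b,
                "n_complaint_intervals": int(len(grp)),
                "n_baseline_intervals": n_base,
            }
        )

    n_candidates = open_t["unit_id"].nunique()
    est = pd.DataFrame(
        rows,
        columns=["unit_id", "A", "D", "SS", "n_complaint_intervals", "n_baseline_intervals"],
    )
    ledger.record("scoring: units meeting complaint and baseline requirements",
                  n_candidates, len(est))
    if len(est) >= 2:
        est["SDS"] = sds_scores(est["SS"])
    elif len(est) == 0:
        raise ValueError("no scoreable units: every unit lacks complaints or baseline")
    else:
        raise ValueError(
            "only one scoreable unit: SDS min-max normalization is undefined"
        )
    meta = unit_table.set_index("unit_id")
    est["zip"] = est["unit_id"].map(meta["zip"])
    est["poi_type"] = est["unit_id"].map(meta["poi_type"])
    return est.reset_index(drop=True), ledger


def aggregate_zip(unit_scores: pd.DataFrame, ledger: FilterLedger | None = None) -> pd.DataFrame:
    """Zip-level mean SDS over a neighborhood's scored units."""
    ledger = ledger or FilterLedger()
    out = (
        unit_scores.groupby("zip", sort=True)
        .agg(SDS_z=("SDS", "mean"), n_units=("unit_id", "size"))
        .reset_index()
    )
    return out


def citywide_complaint_curves(interval_table: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per six-hour slot, complaint vs baseline intervals.

    Only open intervals contribute. Slots with no contributing intervals are
    missing values (NaN), not zeros. The complaint curve sitting above the
    baseline curve is the visual signature of the absolute threshold.
    """
    t = interval_table[interval_table["open"]]
    idx = pd.Index(sorted(t["interval_start"].unique()), name="interval_start")
    comp = (
        t[t["complaint"]].groupby("interval_start")["intensity"].mean().reindex(idx)
    )
    base = (
        t[~t["complaint"]].groupby("interval_start")["intensity"].mean().reindex(idx)
    )
    return pd.DataFrame(
        {"complaint_intensity": comp, "baseline_intensity": base}
    ).reset_index()


def type_summary(
    threshold_estimates: pd.DataFrame,
    unit_table: pd.DataFrame,
    complaint_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Descriptive statistics of the sensitivity measurements per POI type.

    Per type: number of complaint intervals, the share of complaint-receiving
    units of that type among all scored units, the modal complaint hour (when
    complaints are supplied), and mean/sd of A, D and SDS.
    """
    est = threshold_estimates
    g = est.groupby("poi_type")
    out = pd.DataFrame(
        {
            "n_units": g["unit_id"].size(),
            "complaint_volume": g["n_complaint_intervals"].sum(),
            "A_mean": g["A"].mean(),
            "A_sd": g["A"].std(ddof=1),
            "D_mean": g["D"].mean(),
            "D_sd": g["D"].std(ddof=1),
            "SDS_mean": g["SDS"].mean(),
            "SDS_sd": g["SDS"].std(ddof=1),
        }
    )
    out["unit_share_pct"] = out["n_units"] / len(est) * 100.0
    if complaint_table is not None and len(complaint_table):
        from sds.ingest import mode_complaint_hour

        mode = mode_complaint_hour(complaint_table, unit_table)
        out["mode_hour"] = mode
    return out.sort_values("SDS_mean", ascending=False).reset_index()
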
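"""Synthetic city generator with planted reporting-sensitivity structure.

Emulates the statistical shape of the real inputs — POIs with floor areas
and opening hours, Poisson hourly visit streams with a diurnal profile,
occasional crowding bursts, and complaint reports triggered when an
interval's visit density exceeds a neighborhood-specific multiple of that
establishment's running baseline — so that the downstream threshold
estimators can be validated against known ground truth.

Mechanism per six-hour interval of one unit:

1. hourly visits ~ Poisson(base_rate x diurnal[hour] x area scaling), zero
   when closed;
2. with probability ``crowding_burst_prob`` the interval is a *burst*: its
   visit total is inflated by a multiplier drawn uniformly from
   ``burst_multiplier_range`` (rounded to an integer total, extra visits
   apportioned to the interval's hours);
3. the interval *exceeds threshold* when its intensity is greater than
   ``(1 + theta_z)`` times the running mean intensity of the unit's prior
   open, non-burst intervals (the first ``warmup_days`` are a warm-up and
   never trigger);
4. an exceeding interval emits a complaint with probability ``report_prob``,
   time-stamped uniformly within the interval; the complaint carries a
   police-action flag drawn from the zip's ``police_action_prob``.

Because the latent threshold theta_z is known, recovered sensitivity scores
can be checked for rank agreement with the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from sds.config import SyntheticCityConfig

INTERVAL_HOURS = 6
INTERVALS_PER_DAY = 24 // INTERVAL_HOURS

#: Strictly increasing transforms from the standardized latent score to each
#: covariate's natural units (shares in (0,1), income in $, rates per 10k).
_COVARIATE_TRANSFORMS = {
    "median_income": lambda z: 70_000.0 * np.exp(0.30 * z),
    "nh_white_share": lambda z: expit(0.8 * z),
    "black_share": lambda z: 0.6 * expit(0.8 * z),
    "minority_share": lambda z: expit(0.8 * z),
    "republican_share": lambda z: expit(0.8 * z),
    "population_density": lambda z: 40_000.0 * np.exp(0.4 * z),
    "case_rate": lambda z: 2_200.0 + 600.0 * z,
    "vaccination_rate": lambda z: expit(0.8 + 0.5 * z),
}


@dataclass
class GroundTruth:
    """Latent state of a simulated city.

    Attributes
    ----------
    theta : dict
        Planted per-zip reporting threshold (fractional excess over baseline).
    interval_flags : pandas.DataFrame
        One row per (poi_id, interval_start) with boolean columns ``open``,
        ``burst``, ``exceeded``, ``complaint`` and the float ``intensity``.
    police_action : pandas.Series
        Per-complaint boolean flag indexed by complaint_id.
    """

    theta: dict[str, float]
    interval_flags: pd.DataFrame
    police_action: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def validate(self) -> None:
        """Complaints may only occur in threshold-exceeding intervals."""
        bad = self.interval_flags["complaint"] & ~self.interval_flags["exceeded"]
        if bad.any():
            raise AssertionError("complaint emitted without threshold excess")


def _poi_frame(config: SyntheticCityConfig, rng: np.random.Generator) -> pd.DataFrame:
    types = sorted(config.open_hours)
    zips = config.zips
    rows = []
    poi_idx = 0
    for z in zips:
        for _ in range(config.pois_per_zip):
            rows.append(
                {
                    "poi_id": f"p{poi_idx:05d}",
                    "zip": z,
                    "poi_type": types[rng.integers(len(types))],
                    "floor_area": float(
                        np.round(rng.lognormal(*config.floor_area_lognorm), 0)
                    ),
                }
            )
            poi_idx += 1
    poi = pd.DataFrame(rows)
    # Building assignment: one POI per building by default; the pooling
    # stress mode packs 2-3 same-zip POIs into shared buildings.
    if config.pooling_stress:
        # Pack 2-3 POIs per building, never across zip boundaries.
        bids = [""] * len(poi)
        bid = 0
        for _, idx in poi.groupby("zip", sort=True).groups.items():
            i = 0
            idx = list(idx)
            while i < len(idx):
                size = min(int(rng.integers(2, 4)), len(idx) - i)
                for k in range(size):
                    bids[idx[i + k]] = f"B{bid:05d}"
                bid += 1
                i += size
        poi["building_id"] = bids
    else:
        poi["building_id"] = [f"B{i:05d}" for i in range(len(poi))]
    return poi[["poi_id", "building_id", "zip", "poi_type", "floor_area"]]


def generate_city(
    config: SyntheticCityConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a city and return (poi, visits, complaints, covariates, truth).

    The same config (including its seed) reproduces byte-identical tables.
    Tables are plain long-format DataFrames matching the CSV contracts of the
    ingestion stage: ``visits`` has one row per POI per hour of the study
    window with an ``open`` flag; ``complaints`` carries ISO timestamps, the
    building id of the offending unit, a descriptor and a resolution string.
    """
    config = SyntheticCityConfig.model_validate(config)
    master = np.random.SeedSequence(config.seed)
    rng_poi, rng_visits, rng_burst, rng_complaint, rng_police, rng_cov = (
        np.random.default_rng(s) for s in master.spawn(6)
    )

    poi = _poi_frame(config, rng_poi)
    n_pois = len(poi)

    hours = pd.date_range(config.study_start, config.study_end, freq="h", inclusive="left")
    n_hours = len(hours)
    if n_hours % 24:
        raise ValueError("study window must cover whole days")
    hod = hours.hour.to_numpy()
    diurnal = np.asarray(config.diurnal_profile, dtype=float)

    open_lo = poi["poi_type"].map({t: h[0] for t, h in config.open_hours.items()}).to_numpy()
    open_hi = poi["poi_type"].map({t: h[1] for t, h in config.open_hours.items()}).to_numpy()
    open_mask = (hod[None, :] >= open_lo[:, None]) & (hod[None, :] <= open_hi[:, None])

    # Mean hourly visits scale with floor area so intensity, not raw count,
    # is comparable across units; base_rate refers to a 4,000 sq ft unit.
    area_scale = (poi["floor_area"].to_numpy() / 4000.0)[:, None]
    lam = config.base_rate * diurnal[hod][None, :] * area_scale * open_mask
    visits = rng_visits.poisson(lam).astype(np.int64)

    n_intervals = n_hours // INTERVAL_HOURS
    burst = rng_burst.random((n_pois, n_intervals)) < config.crowding_burst_prob
    mult = rng_burst.uniform(*config.burst_multiplier_range, size=(n_pois, n_intervals))

    vis_by_interval = visits.reshape(n_pois, n_intervals, INTERVAL_HOURS)
    totals = vis_by_interval.sum(axis=2)
    # Inflate burst-interval totals: new total = round(total * m); the extra
    # visits are spread over the interval's hours proportionally to the
    # existing counts so the hourly table stays consistent with the totals.
    bi, bj = np.nonzero(burst & (totals > 0))
    for i, j in zip(bi, bj):
        old = totals[i, j]
        new = int(round(old * mult[i, j]))
        extra = new - old
        if extra > 0:
            probs = vis_by_interval[i, j] / old
            add = rng_burst.multinomial(extra, probs)
            vis_by_interval[i, j] += add
            totals[i, j] = new
    visits = vis_by_interval.reshape(n_pois, n_hours)

    areas = poi["floor_area"].to_numpy()
    intensity = totals * 10_000.0 / areas[:, None]
    interval_open = open_mask.reshape(n_pois, n_intervals, INTERVAL_HOURS).any(axis=2)

    # Running baseline: mean intensity of prior open, non-burst intervals.
    eligible = interval_open & ~burst
    csum = np.cumsum(np.where(eligible, intensity, 0.0), axis=1)
    ccnt = np.cumsum(eligible, axis=1)
    prior_sum = np.concatenate([np.zeros((n_pois, 1)), csum[:, :-1]], axis=1)
    prior_cnt = np.concatenate([np.zeros((n_pois, 1), dtype=int), ccnt[:, :-1]], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        baseline = np.where(prior_cnt > 0, prior_sum / np.maximum(prior_cnt, 1), np.nan)

    theta = poi["zip"].map(config.planted_threshold).to_numpy(dtype=float)
    warmup = config.warmup_days * INTERVALS_PER_DAY
    t_idx = np.arange(n_intervals)
    exceeded = (
        interval_open
        & (prior_cnt > 0)
        & (t_idx[None, :] >= warmup)
        & (intensity > (1.0 + theta[:, None]) * baseline)
    )
    # Coupled uniforms: a complaint fires iff exceeded and u < report_prob, so
    # lowering theta can only add complaints for the same seed (monotonicity).
    u = rng_complaint.random((n_pois, n_intervals))
    complaint = exceeded & (u < config.report_prob)

    interval_starts = pd.DatetimeIndex(hours[::INTERVAL_HOURS])
    ci, cj = np.nonzero(complaint)
    offs = rng_complaint.random(len(ci)) * INTERVAL_HOURS * 3600.0
    stamps = interval_starts[cj] + pd.to_timedelta(np.floor(offs), unit="s")
    pa_prob = poi["zip"].map(config.police_action_prob).to_numpy(dtype=float)
    action = rng_police.random(len(ci)) < pa_prob[ci]
    complaints = pd.DataFrame(
        {
            "complaint_id": [f"c{k:06d}" for k in range(len(ci))],
            "timestamp": stamps,
            "building_id": poi["building_id"].to_numpy()[ci],
            "descriptor": "Social Distancing",
            "resolution": np.where(
                action, "Police action was taken", "No action necessary"
            ),
            "police_action": action.astype(int),
        }
    ).sort_values(["timestamp", "complaint_id"], kind="stable").reset_index(drop=True)

    visit_table = pd.DataFrame(
        {
            "poi_id": np.repeat(poi["poi_id"].to_numpy(), n_hours),
            "timestamp": np.tile(hours.to_numpy(), n_pois),
            "visits": visits.ravel(),
            "open": open_mask.ravel().astype(int),
        }
    )

    flags = pd.DataFrame(
        {
            "poi_id": np.repeat(poi["poi_id"].to_numpy(), n_intervals),
            "interval_start": np.tile(interval_starts.to_numpy(), n_pois),
            "open": interval_open.ravel(),
            "burst": burst.ravel(),
            "exceeded": exceeded.ravel(),
            "complaint": complaint.ravel(),
            "intensity": intensity.ravel(),
        }
    )
    truth = GroundTruth(
        theta=dict(config.planted_threshold),
        interval_flags=flags,
        police_action=pd.Series(
            action, index=complaints["complaint_id"], dtype=bool, name="police_action"
        ),
    )
    truth.validate()

    covariates = generate_covariates(config, truth, rng=rng_cov)
    return poi, visit_table, complaints, covariates, truth


def generate_covariates(
    config: SyntheticCityConfig,
    ground_truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Neighborhood covariates as monotone functions of the planted theta.

    Each covariate is a strictly increasing transform of
    ``direction x standardized rank(theta_z) + noise``; with ``noise_scale``
    zero it is therefore a strictly monotone function of theta_z (Spearman
    correlation exactly +/-1). The rank transform keeps the sentinel
    ``theta = inf`` usable.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    zips = config.zips
    theta = np.array([ground_truth.theta[z] for z in zips], dtype=float)
    r = rankdata(theta, method="average")
    sd = r.std()
    z0 = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)

    out = {"zip": zips}
    for name, spec in config.covariate_spec.items():
        if name not in _COVARIATE_TRANSFORMS:
            raise ValueError(f"unknown covariate {name!r}")
        sign = 1.0 if spec.direction == "+" else -1.0
        latent = sign * z0 + rng.normal(0.0, spec.noise_scale, size=len(zips))
        out[name] = _COVARIATE_TRANSFORMS[name](latent)
    return pd.DataFrame(out)
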
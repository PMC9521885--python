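"""Validated configuration objects for the simulator, scorer, and pipeline.

All models reject unknown keys so a typo in a YAML file fails loudly instead
of silently running with a default. Configs round-trip losslessly through
YAML via :meth:`RunConfig.to_yaml` / :meth:`RunConfig.from_yaml`.
"""

from __future__ import annotations

import math
from datetime import datetime
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Covariate names the synthetic generator knows how to produce, mapped to a
#: strictly increasing transform from a standardized latent score to the
#: covariate's natural units. Shares live in (0, 1); rates/incomes are positive.
KNOWN_COVARIATES = (
    "median_income",
    "nh_white_share",
    "black_share",
    "minority_share",
    "republican_share",
    "population_density",
    "case_rate",
    "vaccination_rate",
)


class CovariateSpec(BaseModel):
    """Direction and noise of one synthetic neighborhood covariate.

    direction "+" means the covariate increases with the planted reporting
    threshold theta_z (i.e. with *tolerance*, so it decreases with
    sensitivity); "-" is the reverse. noise_scale is the standard deviation
    of Gaussian noise added on the standardized latent scale before the
    covariate's unit transform is applied.
    """

    model_config = ConfigDict(extra="forbid")

    direction: str
    noise_scale: float = 0.0

    @field_validator("direction")
    @classmethod
    def _check_direction(cls, v: str) -> str:
        if v not in {"+", "-"}:
            raise ValueError(f"direction must be '+' or '-', got {v!r}")
        return v

    @field_validator("noise_scale")
    @classmethod
    def _check_noise(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_scale must be >= 0")
        return v


def _default_diurnal() -> list[float]:
    # Double-peaked urban visit profile: quiet overnight, lunch and early
    # evening peaks. Mean over the 24 entries is ~1 so base_rate keeps its
    # interpretation as mean visits per open hour.
    return [
        0.10, 0.05, 0.05, 0.05, 0.10, 0.25,
        0.50, 0.90, 1.20, 1.30, 1.40, 1.60,
        1.80, 1.60, 1.40, 1.40, 1.50, 1.80,
        2.00, 1.70, 1.20, 0.80, 0.50, 0.25,
    ]


def _default_open_hours() -> dict[str, tuple[int, int]]:
    return {
        "food_drink": (8, 22),
        "store": (9, 19),
        "grocery": (7, 21),
        "hospital_clinic": (0, 23),
        "gym": (6, 21),
        "religious": (8, 18),
    }


def _default_covariates() -> dict[str, CovariateSpec]:
    # Directions mirror the observed disparity pattern: wealthier, whiter,
    # more-vaccinated neighborhoods tolerate less crowding before reporting
    # (low theta), while Republican-leaning and high-case-rate neighborhoods
    # tolerate more (high theta).
    return {
        "median_income": CovariateSpec(direction="-", noise_scale=0.4),
        "nh_white_share": CovariateSpec(direction="-", noise_scale=0.4),
        "black_share": CovariateSpec(direction="+", noise_scale=0.4),
        "minority_share": CovariateSpec(direction="+", noise_scale=0.4),
        "republican_share": CovariateSpec(direction="+", noise_scale=0.4),
        "population_density": CovariateSpec(direction="-", noise_scale=0.4),
        "case_rate": CovariateSpec(direction="+", noise_scale=0.4),
        "vaccination_rate": CovariateSpec(direction="-", noise_scale=0.4),
    }


class SyntheticCityConfig(BaseModel):
    """Parameters of the synthetic city generator.

    The generator plants a per-zip reporting threshold ``theta_z``: a
    complaint can only be triggered in a six-hour interval whose activity
    intensity exceeds ``(1 + theta_z)`` times that unit's running baseline
    mean intensity. ``theta_z = inf`` is a sentinel for "never reports".
    """

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n_zips: int = 20
    pois_per_zip: int = 30
    study_start: datetime = datetime(2020, 3, 28)
    study_end: datetime = datetime(2020, 5, 27)
    base_rate: float = 3.0
    diurnal_profile: list[float] = Field(default_factory=_default_diurnal)
    open_hours: dict[str, tuple[int, int]] = Field(default_factory=_default_open_hours)
    crowding_burst_prob: float = 0.15
    burst_multiplier_range: tuple[float, float] = (1.5, 3.5)
    planted_threshold: Optional[dict[str, float]] = None
    report_prob: float = 0.7
    police_action_prob: Optional[dict[str, float]] = None
    covariate_spec: dict[str, CovariateSpec] = Field(default_factory=_default_covariates)
    seed: int = 0
    warmup_days: int = 2
    pooling_stress: bool = False
    floor_area_lognorm: tuple[float, float] = (8.3, 0.5)

    @field_validator("planted_threshold", mode="before")
    @classmethod
    def _coerce_threshold(cls, v):
        if v is None:
            return v
        # YAML sentinel "never" -> unreachable threshold
        return {
            z: (math.inf if isinstance(t, str) and t.lower() in {"never", "inf"} else float(t))
            for z, t in v.items()
        }

    @model_validator(mode="after")
    def _finalize(self) -> "SyntheticCityConfig":
        if self.n_zips < 2:
            raise ValueError("n_zips must be >= 2")
        if self.pois_per_zip < 1:
            raise ValueError("pois_per_zip must be >= 1")
        if self.study_end <= self.study_start:
            raise ValueError("degenerate date range: study_end <= study_start")
        if (self.study_start.hour, self.study_start.minute) != (0, 0):
            raise ValueError("study_start must fall on a midnight boundary")
        if len(self.diurnal_profile) != 24:
            raise ValueError("diurnal_profile must have exactly 24 entries")
        if any(m < 0 for m in self.diurnal_profile):
            raise ValueError("diurnal_profile entries must be non-negative")
        if not self.open_hours:
            raise ValueError("open_hours must name at least one POI type")
        for t, (a, b) in self.open_hours.items():
            if not (0 <= a <= b <= 23):
                raise ValueError(f"open_hours for {t!r} must satisfy 0 <= open <= close <= 23")
        for name, p in [
            ("crowding_burst_prob", self.crowding_burst_prob),
            ("report_prob", self.report_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.burst_multiplier_range
        if not (1.0 < lo <= hi):
            raise ValueError("burst multipliers must be > 1 with low <= high")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")

        zips = [f"z{i:03d}" for i in range(self.n_zips)]
        if self.planted_threshold is None:
            # Spread tolerances across neighborhoods: theta from 5% to 120%
            # excess over baseline before anyone reports.
            thetas = [0.05 + 1.15 * i / (self.n_zips - 1) for i in range(self.n_zips)]
            object.__setattr__(self, "planted_threshold", dict(zip(zips, thetas)))
        if self.police_action_prob is None:
            object.__setattr__(
                self, "police_action_prob", {z: 0.45 for z in self.planted_threshold}
            )
        if set(self.police_action_prob) != set(self.planted_threshold):
            raise ValueError("police_action_prob and planted_threshold must cover the same zips")
        if len(self.planted_threshold) != self.n_zips:
            raise ValueError("planted_threshold must name exactly n_zips zips")
        for z, t in self.planted_threshold.items():
            if not (t >= 0):
                raise ValueError(f"theta for zip {z} must be >= 0")
        for z, p in self.police_action_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"police_action_prob for zip {z} must be in [0, 1]")
        for name in self.covariate_spec:
            if name not in KNOWN_COVARIATES:
                raise ValueError(
                    f"unknown covariate {name!r}; known: {', '.join(KNOWN_COVARIATES)}"
                )
        return self

    @property
    def zips(self) -> list[str]:
        return sorted(self.planted_threshold)


class ScoreConfig(BaseModel):
    """Scoring options for the threshold/SDS stage."""

    model_config = ConfigDict(extra="forbid")

    #: Log base in the sensation law SS = D x log_b(A). SDS is invariant to
    #: this choice (min-max normalization absorbs the positive constant).
    log_base: float = 10.0
    #: Minimum number of open, complaint-free intervals a unit needs before
    #: its baseline mean is trusted (about one day's worth).
    min_baseline: int = 4
    #: Match each complaint interval's baseline to the same time-of-day slot
    #: instead of pooling all baseline intervals. Off by default.
    stratify_baseline: bool = False
    #: Intensity is reported per this much floor area (sq ft).
    intensity_scale: float = 10000.0

    @field_validator("log_base")
    @classmethod
    def _check_base(cls, v: float) -> float:
        if v <= 1.0:
            raise ValueError("log_base must be > 1")
        return v

    @field_validator("min_baseline")
    @classmethod
    def _check_min_baseline(cls, v: int) -> int:
        if v < 1:
            raise ValueError("min_baseline must be >= 1")
        return v


class AnalysisConfig(BaseModel):
    """Options for the neighborhood disparity analysis."""

    model_config = ConfigDict(extra="forbid")

    police_low: float = 0.3
    police_high: float = 0.6
    demographic_col: str = "nh_white_share"
    indicators: list[str] = ["case_rate", "vaccination_rate"]

    @model_validator(mode="after")
    def _check_thresholds(self) -> "AnalysisConfig":
        if not (0.0 < self.police_low < self.police_high < 1.0):
            raise ValueError("police thresholds must satisfy 0 < low < high < 1")
        return self


class RunConfig(BaseModel):
    """One end-to-end pipeline run: simulate -> ingest -> score -> analyze."""

    model_config = ConfigDict(extra="forbid")

    synthetic: Optional[SyntheticCityConfig] = None
    poi_path: Optional[str] = None
    visits_path: Optional[str] = None
    complaints_path: Optional[str] = None
    covariates_path: Optional[str] = None
    zips_geojson: Optional[str] = None
    score: ScoreConfig = ScoreConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    out_dir: str = "results"
    seed: int = 0

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        file_inputs = (self.poi_path, self.visits_path, self.complaints_path)
        if self.synthetic is None and any(p is None for p in file_inputs):
            raise ValueError(
                "either a synthetic config or poi/visits/complaints paths are required"
            )
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text))
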
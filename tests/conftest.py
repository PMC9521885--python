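"""Shared fixtures: small synthetic cities and the two-case worked example."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from sds.config import SyntheticCityConfig
from sds.synthetic import generate_city

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def small_city_config(**overrides) -> SyntheticCityConfig:
    defaults = dict(
        n_zips=4,
        pois_per_zip=10,
        study_start="2020-03-28",
        study_end="2020-04-11",
        seed=1,
    )
    defaults.update(overrides)
    return SyntheticCityConfig(**defaults)


@pytest.fixture(scope="session")
def small_city():
    """A 4-zip, 14-day city: (config, poi, visits, complaints, covariates, truth)."""
    cfg = small_city_config()
    return (cfg, *generate_city(cfg))


@pytest.fixture(scope="session")
def default_city():
    """The shipped default city: 20 zips x 30 POIs x 60 days, seed 0."""
    cfg = SyntheticCityConfig()
    return (cfg, *generate_city(cfg))


def two_case_intervals() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two-establishment worked example as an interval table.

    Both units have 10,000 sq ft, a baseline of 4 visits per interval over
    four complaint-free intervals, and one complaint interval each with 20
    (unit "caseB") and 6 (unit "caseC") visits, so intensities read directly
    as visit counts.
    """
    rows = []
    starts = pd.date_range("2020-04-01", periods=5, freq="6h")
    for unit, peak in [("caseB", 20), ("caseC", 6)]:
        for s in starts[:4]:
            rows.append({"unit_id": unit, "interval_start": s, "visits": 4,
                         "open": True, "complaint": False})
        rows.append({"unit_id": unit, "interval_start": starts[4], "visits": peak,
                     "open": True, "complaint": True})
    intervals = pd.DataFrame(rows)
    units = pd.DataFrame(
        {
            "unit_id": ["caseB", "caseC"],
            "floor_area": [10_000.0, 10_000.0],
            "zip": ["z1", "z1"],
            "poi_type": ["food_drink", "food_drink"],
            "n_pois_pooled": [1, 1],
        }
    )
    return intervals, units
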
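import math

import numpy as np
import pandas as pd
import pytest

from pahrisk import (
    CONGENER_NAMES,
    LognormalSpec,
    NormalSpec,
    PopulationGroup,
    PopulationStratum,
    validate_congener_table,
)

HOURS_70_YEARS = 70.0 * 365.0 * 24.0


def table_from_conc(
    conc: dict[str, float], sample_id: str = "s1", city: str = "HZ",
    date: str = "2015-01-12",
) -> pd.DataFrame:
    """Tiny one-sample congener table; congeners absent from ``conc`` get 0."""
    rows = [
        {
            "sample_id": sample_id,
            "city": city,
            "date": date,
            "congener": name,
            "conc_ng_m3": conc.get(name, 0.0),
            "below_detection": 0,
            "lod_ng_m3": np.nan,
        }
        for name in CONGENER_NAMES
    ]
    return validate_congener_table(pd.DataFrame(rows))


def point_lognormal(value: float) -> LognormalSpec:
    return LognormalSpec(mu=math.log(value), sigma=0.0)


def point_et(hours: float) -> NormalSpec:
    return NormalSpec(hours, 0.0, lower=0.0, upper=24.0)


def make_group(
    *,
    city: str = "HZ",
    age_group: str = "adult",
    gender: str = "male",
    ir: float = 10.0,
    et: NormalSpec | None = None,
    bw: float | NormalSpec = 60.0,
    ed: float = 70.0,
    ef: float = 365.0,
    at_hours: float = HOURS_70_YEARS,
    cf: float = 1e-9,
    csf: LognormalSpec | None = None,
) -> PopulationGroup:
    """Exposure group with degenerate defaults, overridable per test."""
    return PopulationGroup(
        stratum=PopulationStratum(city, age_group, gender),
        ir_m3_day=ir,
        et=et if et is not None else point_et(12.0),
        bw_kg=bw,
        ed_years=ed,
        ef_days_year=ef,
        at_hours=at_hours,
        cf_mg_per_pg=cf,
        csf=csf if csf is not None else point_lognormal(3.14),
    )


@pytest.fixture
def degenerate_group() -> PopulationGroup:
    return make_group()


@pytest.fixture
def stochastic_adult_group() -> PopulationGroup:
    return make_group(
        et=NormalSpec(4.0, 2.0, lower=0.0, upper=24.0),
        csf=LognormalSpec(mu=math.log(3.14), sigma=math.log(1.80)),
    )


@pytest.fixture
def stochastic_child_group() -> PopulationGroup:
    return make_group(
        age_group="child",
        et=NormalSpec(4.0, 2.0, lower=0.0, upper=24.0),
        bw=NormalSpec(33.0, 7.0, lower=10.0, upper=100.0),
        ed=10.0,
        csf=LognormalSpec(mu=math.log(3.14), sigma=math.log(1.80)),
    )
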
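from __future__ import annotations

import pytest

from hospilink import FacilityRecord, RunConfig, YearCohort


def rec(record_id, year, iic, sc="01", lat=50.0, lon=8.0, municipality="Marburg", **attrs):
    return FacilityRecord(
        record_id=record_id,
        year=year,
        iic=iic,
        sc=sc,
        lat=lat,
        lon=lon,
        municipality=municipality,
        attributes=attrs,
    )


def cohort(year, records):
    return YearCohort(year=year, records=records)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def single_pair_cohorts():
    """One identical facility in both years: the maximal-similarity case."""
    c1 = cohort(2016, [rec("A", 2016, "X")])
    c2 = cohort(2017, [rec("B", 2017, "X")])
    return c1, c2
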
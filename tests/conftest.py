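from __future__ import annotations

import json
from datetime import date

import pytest
from hypothesis import settings

from remotepop.occupancy import Method, OccupancyReport, Provenance, Unit

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

ANALYSIS_DATE = date(2010, 1, 29)


def make_report(report_id="r1", value=6.0, unit=Unit.PER_STRUCTURE,
                provenance=Provenance.SITE_CURRENT,
                method=Method.CENSUS_REGISTRATION_SURVEILLANCE,
                years_before=1, **kw) -> OccupancyReport:
    collection = kw.pop(
        "collection_date",
        date(ANALYSIS_DATE.year - years_before, ANALYSIS_DATE.month, ANALYSIS_DATE.day),
    )
    return OccupancyReport(
        report_id=report_id, occupancy_value=value, unit=unit,
        provenance=provenance, method=method, collection_date=collection, **kw,
    )


@pytest.fixture
def analysis_date() -> date:
    return ANALYSIS_DATE


@pytest.fixture
def geojson_marks(tmp_path):
    """Three-point GeoJSON file: analyst A, two huts and a latrine."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": {"type": "Point", "coordinates": [10.0, 20.0]},
             "properties": {"analyst_id": "A", "category": "hut"}},
            {"type": "Feature", "geometry": {"type": "Point", "coordinates": [30.0, 40.0]},
             "properties": {"analyst_id": "A", "category": "hut"}},
            {"type": "Feature", "geometry": {"type": "Point", "coordinates": [50.0, 60.0]},
             "properties": {"analyst_id": "A", "category": "latrine"}},
        ],
    }
    p = tmp_path / "marks.geojson"
    p.write_text(json.dumps(doc))
    return p


@pytest.fixture
def category_map():
    return {"hut": True, "tent": True, "latrine": False}
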
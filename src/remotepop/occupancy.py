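"""Occupancy reports, eligibility screening and hierarchy-of-evidence scoring.

Occupancy information — how many people live in one residential structure,
or one household — comes from a heterogeneous literature: registration
exercises, household surveys, rapid assessments, anecdote. Each report is
screened for eligibility (recency, full text, primary data, urban match for
urban sites) and then scored on three attributes:

1. representativeness of the site and analysis time point (10/8/4/2),
2. robustness of the data-collection method (10/8/6/4/1),
3. whether the unit is a residential structure or a household (10/6/1).

A report's *information score* is the product of the three point values,
so it ranges from 2 to a maximum of 1000; the site-level *amount of
information index* is the sum of scores over all eligible reports.

Point values live in a packaged, versioned rubric file so the hierarchy can
be refined without code change; the default rubric is the published one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "Unit",
    "Provenance",
    "Method",
    "SiteKind",
    "SamplingScheme",
    "SurveyDesign",
    "OccupancyReport",
    "EvidenceScore",
    "Exclusion",
    "Rubric",
    "load_rubric",
    "filter_eligible",
    "classify_representativeness",
    "classify_method",
    "classify_unit",
    "information_score",
    "information_index",
]


class Unit(str, Enum):
    """What one occupancy value counts people per."""

    PER_STRUCTURE = "per_structure"
    PER_HOUSEHOLD_CONSISTENT_WITH_STRUCTURE = "per_household_consistent_with_structure"
    PER_HOUSEHOLD_OTHER = "per_household_other"


class Provenance(str, Enum):
    """Where and when, relative to the site and crisis, the data were collected."""

    SITE_CURRENT = "site_current"
    REGION_CURRENT = "region_current"
    SITE_OR_REGION_PREVIOUS = "site_or_region_previous"
    PRE_DISPLACEMENT = "pre_displacement"


class Method(str, Enum):
    CENSUS_REGISTRATION_SURVEILLANCE = "census_registration_surveillance"
    LARGE_SURVEY = "large_survey"
    OTHER_SURVEY = "other_survey"
    RAPID_ASSESSMENT = "rapid_assessment"
    ANECDOTAL = "anecdotal"


class SiteKind(str, Enum):
    CAMP = "camp"
    URBAN = "urban"


class SamplingScheme(str, Enum):
    SIMPLE = "simple"
    SYSTEMATIC = "systematic"
    CLUSTER = "cluster"


@dataclass(frozen=True)
class SurveyDesign:
    """Survey design details, used to decide whether a survey counts as large."""

    scheme: SamplingScheme
    n_households: int
    n_clusters: int | None = None
    has_technical_flaw: bool = False

    def __post_init__(self) -> None:
        if self.n_households < 0:
            raise ValueError("n_households must be >= 0")
        if self.scheme == SamplingScheme.CLUSTER and self.n_clusters is None:
            raise ValueError("cluster designs require n_clusters")


@dataclass
class OccupancyReport:
    """One literature estimate of household size or structure occupancy."""

    report_id: str
    occupancy_value: float
    unit: Unit
    provenance: Provenance
    method: Method | None = None
    survey_design: SurveyDesign | None = None
    collection_date: date | None = None
    citation: str = ""
    full_text_available: bool = True
    has_primary_data: bool = True
    urban_population: bool = True  # does the report reflect urban populations only?

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.occupancy_value > 0:
            raise ValueError(f"occupancy_value must be > 0, got {self.occupancy_value}")
        self.unit = Unit(self.unit)
        self.provenance = Provenance(self.provenance)
        if self.method is not None:
            self.method = Method(self.method)


@dataclass(frozen=True)
class EvidenceScore:
    """Per-attribute points and their product, the report's evidence weight."""

    points_representativeness: int
    points_method: int
    points_unit: int

    @property
    def score(self) -> int:
        return self.points_representativeness * self.points_method * self.points_unit


@dataclass(frozen=True)
class Exclusion:
    report_id: str
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class Rubric:
    version: str
    representativeness: dict[str, int]
    method: dict[str, int]
    unit: dict[str, int]
    large_survey_thresholds: dict[str, int]
    current_window_years: int = 3
    eligible_window_years: int = 10


def load_rubric(version: str = "1") -> Rubric:
    """Load a packaged rubric definition by version."""
    name = f"rubric_v{version}.json"
    try:
        raw = json.loads(resources.files("remotepop.data").joinpath(name).read_text())
    except FileNotFoundError:
        raise ValueError(f"no packaged rubric version {version!r}") from None
    return Rubric(
        version=raw["version"],
        representativeness=raw["representativeness"],
        method=raw["method"],
        unit=raw["unit"],
        large_survey_thresholds=raw["large_survey_thresholds"],
        current_window_years=raw["windows_years"]["current"],
        eligible_window_years=raw["windows_years"]["eligible"],
    )


_DEFAULT_RUBRIC: Rubric | None = None


def _default_rubric() -> Rubric:
    global _DEFAULT_RUBRIC
    if _DEFAULT_RUBRIC is None:
        _DEFAULT_RUBRIC = load_rubric("1")
    return _DEFAULT_RUBRIC


def _years_before(d: date, n: int) -> date:
    """Same calendar day n years earlier; 29 Feb falls back to 28 Feb."""
    try:
        return d.replace(year=d.year - n)
    except ValueError:
        return d.replace(year=d.year - n, day=28)


def _within_years(collection: date, analysis: date, years: int) -> bool:
    # whole-day arithmetic, boundary inclusive: exactly `years` ago counts
    return _years_before(analysis, years) <= collection <= analysis


def filter_eligible(
    reports: Iterable[OccupancyReport],
    site_kind: SiteKind | str,
    analysis_date: date,
) -> tuple[list[OccupancyReport], list[Exclusion]]:
    """Screen reports for eligibility; return the eligible subset and an exclusion log.

    Rules: the report must carry a collection date within the 10-year window
    before the analysis date; the full text must have been available and
    contain primary occupancy data; and for urban sites the report must
    reflect urban populations only. Every exclusion is logged with all the
    rules it violated. The filter is idempotent.
    """
    site_kind = SiteKind(site_kind)
    rubric = _default_rubric()
    eligible: list[OccupancyReport] = []
    excluded: list[Exclusion] = []
    for r in reports:
        reasons: list[str] = []
        if r.collection_date is None:
            reasons.append("undated")
        elif r.collection_date > analysis_date:
            reasons.append("collected after analysis date")
        elif not _within_years(r.collection_date, analysis_date, rubric.eligible_window_years):
            reasons.append(f"older than {rubric.eligible_window_years}y window")
        if not r.full_text_available:
            reasons.append("full text unavailable")
        if not r.has_primary_data:
            reasons.append("no primary occupancy data")
        if site_kind == SiteKind.URBAN and not r.urban_population:
            reasons.append("non-urban")
        if reasons:
            excluded.append(Exclusion(report_id=r.report_id, reasons=tuple(reasons)))
        else:
            eligible.append(r)
    return eligible, excluded


def classify_representativeness(
    report: OccupancyReport,
    analysis_date: date,
    rubric: Rubric | None = None,
) -> int:
    """Points for how representative the report is of the site at the analysis date.

    Site itself within 3 years -> 10; same crisis region within 3 years -> 8;
    site or region but 3-10 years before -> 4; pre-displacement conditions
    within 10 years -> 2. A report labelled as current whose collection date
    falls in the 3-10 year window is demoted to the previous-period level.
    """
    rubric = rubric or _default_rubric()
    if report.collection_date is None:
        raise ValueError(f"report {report.report_id}: no collection date (run filter_eligible first)")
    if not _within_years(report.collection_date, analysis_date, rubric.eligible_window_years):
        raise ValueError(
            f"report {report.report_id}: collection date outside the "
            f"{rubric.eligible_window_years}y window (should have been filtered)"
        )
    prov = report.provenance
    current = _within_years(report.collection_date, analysis_date, rubric.current_window_years)
    if prov in (Provenance.SITE_CURRENT, Provenance.REGION_CURRENT) and not current:
        prov = Provenance.SITE_OR_REGION_PREVIOUS
    return rubric.representativeness[prov.value]


def classify_method(report: OccupancyReport, rubric: Rubric | None = None) -> int:
    """Points for the robustness of the data-collection method.

    Census/registration/surveillance -> 10; a *large* survey with no obvious
    technical flaw -> 8; any other survey or cross-sectional sample -> 6;
    rapid assessment, site visit or programmatic review -> 4; anecdote -> 1.

    "Large" is decided from the survey design when one is supplied, with
    strict thresholds: >200 households for simple/systematic sampling, or
    >400 households *and* >20 clusters for cluster sampling.
    """
    rubric = rubric or _default_rubric()
    design = report.survey_design
    survey_tiers = (Method.LARGE_SURVEY, Method.OTHER_SURVEY, None)
    if design is not None and report.method in survey_tiers:
        t = rubric.large_survey_thresholds
        if design.scheme == SamplingScheme.CLUSTER:
            large = (
                design.n_households > t["cluster_min_households"]
                and design.n_clusters is not None
                and design.n_clusters > t["cluster_min_clusters"]
            )
        else:
            large = design.n_households > t["simple_systematic_min_households"]
        if design.has_technical_flaw:
            large = False
        return rubric.method[Method.LARGE_SURVEY.value if large else Method.OTHER_SURVEY.value]
    if report.method is None:
        raise ValueError(f"report {report.report_id}: neither method level nor survey design supplied")
    return rubric.method[report.method.value]


def classify_unit(report: OccupancyReport, rubric: Rubric | None = None) -> int:
    """Points for unit congruence: structures 10, structure-consistent households 6, other 1."""
    rubric = rubric or _default_rubric()
    return rubric.unit[report.unit.value]


def information_score(
    report: OccupancyReport,
    analysis_date: date,
    rubric: Rubric | None = None,
) -> EvidenceScore:
    """Score an eligible report: the product of its three attribute point values."""
    rubric = rubric or _default_rubric()
    return EvidenceScore(
        points_representativeness=classify_representativeness(report, analysis_date, rubric),
        points_method=classify_method(report, rubric),
        points_unit=classify_unit(report, rubric),
    )


def information_index(scores: Iterable[EvidenceScore | int]) -> int:
    """Amount-of-information index: the sum of report scores (0 if none)."""
    return sum(s.score if isinstance(s, EvidenceScore) else int(s) for s in scores)
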
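"""Eligibility screening and hierarchy-of-evidence scoring of occupancy reports."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from remotepop.occupancy import (
    Method,
    Provenance,
    SamplingScheme,
    SiteKind,
    SurveyDesign,
    Unit,
    classify_method,
    classify_representativeness,
    classify_unit,
    filter_eligible,
    information_index,
    information_score,
    load_rubric,
)

from .conftest import ANALYSIS_DATE, make_report


class TestEligibility:
    def test_recent_camp_report_is_eligible(self, analysis_date):
        eligible, excluded = filter_eligible([make_report(years_before=2)], SiteKind.CAMP, analysis_date)
        assert len(eligible) == 1 and not excluded

    def test_stale_report_excluded_with_reason(self, analysis_date):
        _, excluded = filter_eligible([make_report(years_before=12)], SiteKind.CAMP, analysis_date)
        assert excluded[0].reasons == ("older than 10y window",)

    def test_rural_report_excluded_for_urban_site(self, analysis_date):
        r = make_report(urban_population=False)
        eligible_camp, _ = filter_eligible([r], SiteKind.CAMP, analysis_date)
        _, excluded_urban = filter_eligible([r], SiteKind.URBAN, analysis_date)
        assert eligible_camp == [r]
        assert "non-urban" in excluded_urban[0].reasons

    def test_undated_and_secondary_reports_excluded(self, analysis_date):
        undated = make_report(report_id="u", collection_date=None)
        secondary = make_report(report_id="s", has_primary_data=False)
        abstract_only = make_report(report_id="a", full_text_available=False)
        eligible, excluded = filter_eligible(
            [undated, secondary, abstract_only], SiteKind.CAMP, analysis_date
        )
        assert eligible == []
        reasons = {e.report_id: e.reasons for e in excluded}
        assert reasons["u"] == ("undated",)
        assert reasons["s"] == ("no primary occupancy data",)
        assert reasons["a"] == ("full text unavailable",)

    def test_boundary_exactly_ten_years_is_within(self, analysis_date):
        r = make_report(collection_date=date(2000, 1, 29))
        eligible, _ = filter_eligible([r], SiteKind.CAMP, analysis_date)
        assert eligible == [r]

    def test_filter_is_idempotent(self, analysis_date):
        reports = [make_report(report_id=f"r{i}", years_before=i) for i in (1, 5, 12)]
        once, _ = filter_eligible(reports, SiteKind.CAMP, analysis_date)
        twice, excluded = filter_eligible(once, SiteKind.CAMP, analysis_date)
        assert twice == once and not excluded


class TestRepresentativeness:
    @pytest.mark.parametrize(
        "provenance,years,points",
        [(Provenance.SITE_CURRENT, 1, 10),
         (Provenance.REGION_CURRENT, 2, 8),
         (Provenance.SITE_CURRENT, 5, 4),  # dated outside the 3y window: demoted
         (Provenance.SITE_OR_REGION_PREVIOUS, 5, 4),
         (Provenance.PRE_DISPLACEMENT, 4, 2)],
    )
    def test_points(self, provenance, years, points, analysis_date):
        r = make_report(provenance=provenance, years_before=years)
        assert classify_representativeness(r, analysis_date) == points

    def test_exactly_three_years_counts_as_current(self, analysis_date):
        r = make_report(collection_date=date(2007, 1, 29))
        assert classify_representativeness(r, analysis_date) == 10

    def test_out_of_window_date_raises(self, analysis_date):
        r = make_report(years_before=12)
        with pytest.raises(ValueError, match="10y window"):
            classify_representativeness(r, analysis_date)


class TestMethodPoints:
    def test_registration_scores_ten(self):
        assert classify_method(make_report(method=Method.CENSUS_REGISTRATION_SURVEILLANCE)) == 10

    @pytest.mark.parametrize(
        "design,points",
        [(SurveyDesign(SamplingScheme.CLUSTER, 450, 30), 8),
         (SurveyDesign(SamplingScheme.CLUSTER, 450, 20), 6),   # 20 clusters is not >20
         (SurveyDesign(SamplingScheme.CLUSTER, 400, 30), 6),   # 400 households is not >400
         (SurveyDesign(SamplingScheme.SIMPLE, 201, None), 8),
         (SurveyDesign(SamplingScheme.SIMPLE, 200, None), 6),  # strict threshold
         (SurveyDesign(SamplingScheme.SYSTEMATIC, 500, None, has_technical_flaw=True), 6)],
    )
    def test_large_survey_thresholds_are_strict(self, design, points):
        r = make_report(method=Method.LARGE_SURVEY, survey_design=design)
        assert classify_method(r) == points

    @pytest.mark.parametrize(
        "method,points",
        [(Method.OTHER_SURVEY, 6), (Method.RAPID_ASSESSMENT, 4), (Method.ANECDOTAL, 1)],
    )
    def test_stated_levels(self, method, points):
        assert classify_method(make_report(method=method)) == points

    def test_cluster_without_n_clusters_errors(self):
        with pytest.raises(ValueError, match="n_clusters"):
            SurveyDesign(SamplingScheme.CLUSTER, 450)

    def test_no_method_and_no_design_errors(self):
        with pytest.raises(ValueError, match="neither"):
            classify_method(make_report(method=None))


class TestUnitPoints:
    @pytest.mark.parametrize(
        "unit,points",
        [(Unit.PER_STRUCTURE, 10),
         (Unit.PER_HOUSEHOLD_CONSISTENT_WITH_STRUCTURE, 6),
         (Unit.PER_HOUSEHOLD_OTHER, 1)],
    )
    def test_points(self, unit, points):
        assert classify_unit(make_report(unit=unit)) == points


class TestInformationScore:
    @pytest.mark.parametrize(
        "provenance,method,unit,years,score",
        [(Provenance.SITE_CURRENT, Method.CENSUS_REGISTRATION_SURVEILLANCE, Unit.PER_STRUCTURE, 1, 1000),
         (Provenance.PRE_DISPLACEMENT, Method.ANECDOTAL, Unit.PER_HOUSEHOLD_OTHER, 4, 2),
         (Provenance.SITE_OR_REGION_PREVIOUS, Method.RAPID_ASSESSMENT, Unit.PER_HOUSEHOLD_OTHER, 5, 16)],
    )
    def test_products(self, provenance, method, unit, years, score, analysis_date):
        r = make_report(provenance=provenance, method=method, unit=unit, years_before=years)
        assert information_score(r, analysis_date).score == score

    def test_score_factors_into_legal_points(self, analysis_date):
        rubric = load_rubric()
        s = information_score(make_report(), analysis_date)
        assert s.points_representativeness in rubric.representativeness.values()
        assert s.points_method in rubric.method.values()
        assert s.points_unit in rubric.unit.values()
        assert 2 <= s.score <= 1000

    @given(
        prov=st.sampled_from(list(Provenance)),
        meth=st.sampled_from(list(Method)),
        unit=st.sampled_from(list(Unit)),
    )
    def test_monotone_in_each_attribute(self, prov, meth, unit, ):
        """Improving one attribute, others fixed, never lowers the score."""
        when = ANALYSIS_DATE
        years = {Provenance.SITE_CURRENT: 1, Provenance.REGION_CURRENT: 1,
                 Provenance.SITE_OR_REGION_PREVIOUS: 5, Provenance.PRE_DISPLACEMENT: 5}

        def score(p, m, u):
            return information_score(
                make_report(provenance=p, method=m, unit=u, years_before=years[p]), when
            ).score

        base = score(prov, meth, unit)
        assert score(Provenance.SITE_CURRENT, meth, unit) >= base
        assert score(prov, Method.CENSUS_REGISTRATION_SURVEILLANCE, unit) >= base
        assert score(prov, meth, Unit.PER_STRUCTURE) >= base


class TestInformationIndex:
    def test_singleton_index_equals_score(self):
        assert information_index([16]) == 16

    def test_sum_and_empty(self):
        assert information_index([1000, 2]) == 1002
        assert information_index([]) == 0

    @given(st.lists(st.integers(2, 1000), max_size=12))
    def test_permutation_invariant_and_additive(self, scores):
        assert information_index(scores) == information_index(list(reversed(scores)))
        k = len(scores) // 2
        assert information_index(scores) == information_index(scores[:k]) + information_index(scores[k:])
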
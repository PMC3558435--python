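{
  "version": "1",
  "description": "Hierarchy of evidence for structure-occupancy reports: points for representativeness, data-collection method robustness, and unit congruence; a report's information score is the product of its three point values (maximum 1000).",
  "representativeness": {
    "site_current": 10,
    "region_current": 8,
    "site_or_region_previous": 4,
    "pre_displacement": 2
  },
  "method": {
    "census_registration_surveillance": 10,
    "large_survey": 8,
    "other_survey": 6,
    "rapid_assessment": 4,
    "anecdotal": 1
  },
  "unit": {
    "per_structure": 10,
    "per_household_consistent_with_structure": 6,
    "per_household_other": 1
  },
  "large_survey_thresholds": {
    "simple_systematic_min_households": 200,
    "cluster_min_households": 400,
    "cluster_min_clusters": 20
  },
  "windows_years": {
    "current": 3,
    "eligible": 10
  }
}
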
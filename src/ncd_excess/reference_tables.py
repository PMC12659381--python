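"""Published point estimates from the Gaza NCD projection exercise.

These are the published mean excess-death estimates this model family
produced for the Gaza Strip (war onset 7 October 2023; six-month
projection horizon from 7 February 2024), by disease category, by age
stratum, scenario and sub-period.  They serve as reference inputs for
the aggregation utilities: category sums reproduce the published totals
and the age tables yield the published >=50-year-old shares.
"""

from __future__ import annotations

from .config_io import AGE_STRATA

__all__ = [
    "EXCESS_BY_DISEASE_TO_DATE",
    "EXCESS_BY_DISEASE_M1_3",
    "EXCESS_BY_AGE_TOTAL",
    "PUBLISHED_TOTALS",
    "DM1_SHARE_OF_DM_INCIDENCE",
    "DM_INCIDENT_CASES_PER_MONTH",
]

#: mean excess deaths 7 Oct 2023 - 6 Feb 2024 (pre-projection period)
EXCESS_BY_DISEASE_TO_DATE = {
    "ischaemic_heart_disease": 1242,
    "chronic_kidney_disease": 33,
    "diabetes_mellitus_type_1": 27,
    "stroke": 115,
    "cancer": 62,
}

#: mean excess deaths, projection months 1-3, by scenario
EXCESS_BY_DISEASE_M1_3 = {
    "ceasefire": {
        "ischaemic_heart_disease": 776,
        "chronic_kidney_disease": 21,
        "diabetes_mellitus_type_1": 18,
        "stroke": 70,
        "cancer": 30,
    },
    "status_quo": {
        "ischaemic_heart_disease": 992,
        "chronic_kidney_disease": 34,
        "diabetes_mellitus_type_1": 97,
        "stroke": 92,
        "cancer": 46,
    },
    "escalation": {
        "ischaemic_heart_disease": 1044,
        "chronic_kidney_disease": 39,
        "diabetes_mellitus_type_1": 141,
        "stroke": 99,
        "cancer": 45,
    },
}

#: mean excess deaths over the six-month projection, by age stratum
EXCESS_BY_AGE_TOTAL = {
    "ceasefire": dict(zip(AGE_STRATA, (2, 6, 15, 30, 94, 217, 322, 409, 585))),
    "status_quo": dict(zip(AGE_STRATA, (12, 26, 44, 61, 164, 325, 464, 576, 807))),
    "escalation": dict(zip(AGE_STRATA, (18, 38, 58, 73, 188, 352, 494, 609, 847))),
}

#: published category totals the disease tables sum to
PUBLISHED_TOTALS = {
    "to_date": 1479,
    "m1_3": {"ceasefire": 915, "status_quo": 1261, "escalation": 1368},
}

#: type-1 share of pre-war incident diabetes cases, and mean DM incidence
DM1_SHARE_OF_DM_INCIDENCE = 0.03
DM_INCIDENT_CASES_PER_MONTH = 17.0
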
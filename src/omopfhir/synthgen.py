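"""Seeded synthetic OMOP CDM v5.3 generator.

Produces all 11 tables the pipeline consumes, referentially consistent and
byte-identical for a fixed seed, with targeted edge-case injection at
configurable rates (missing requester, inverted coverage period, 4-digit
zip, under-age person, pre-2017-only visits, ...).  Value distributions are
simple Poisson/uniform draws — the generator emulates *structure* (joins,
concept resolution, survey multi-rows, routing variety), not clinical
realism.

One structural guarantee: every drug route (prescription written,
inpatient administration, pharmacy dispense, patient-reported, CVX
vaccine) appears at least once per run, pinned to the first
cohort-eligible person, so a full pipeline run always exercises all ten
FHIR resource types regardless of seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Union

import numpy as np

from .omop_store import EXPECTED_COLUMNS, OmopJsonDocument

__all__ = ["SynthConfig", "generate", "worked_example_fixture", "WORKED_SMOKING_STRING"]

#: The printed 9-component smoking concatenation used as a golden fixture.
WORKED_SMOKING_STRING = (
    "(Chew:No) – (CigarettePacksPerDay:<20) – (Cigarettes:No) – (Cigars:No) – "
    "(Nicotine dependence, cigarettes, uncomplicated) – (Pipes:No) – "
    "(Snuff:No) – (TobaccoUse:Yes) – (TobaccoUseInYears:+)"
)

_DEFAULT_EDGE_RATES: dict[str, float] = {
    "missing_requester": 0.02,
    "stop_reason_present": 0.30,
    "overlapping_coverage": 0.25,
    "inverted_period": 0.005,
    "missing_zip": 0.05,
    "under_age": 0.03,
    "pre_2017_only": 0.05,
    "multi_row_smoking": 0.50,
    "non_cvx_vaccine": 0.10,
}


@dataclass
class SynthConfig:
    n_persons: int = 100
    seed: int = 7
    date_range: tuple[date, date] = (date(2017, 1, 1), date(2022, 12, 1))
    reference_date: date = date(2023, 1, 1)  # ages computed against this
    edge_rates: dict[str, float] = field(default_factory=dict)
    smoking_rows_per_survey_max: int = 10

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 1 <= self.smoking_rows_per_survey_max <= 10:
            raise ValueError("smoking_rows_per_survey_max must be in 1..10")
        rates = dict(_DEFAULT_EDGE_RATES)
        unknown = set(self.edge_rates) - set(rates)
        if unknown:
            raise KeyError(f"unknown edge rates: {sorted(unknown)}")
        rates.update(self.edge_rates)
        for name, p in rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge rate {name} must be in [0, 1]")
        self.edge_rates = rates

    @classmethod
    def clean(cls, n_persons: int = 100, seed: int = 7, **kw) -> "SynthConfig":
        """All defect-injection rates zeroed (the clean-data condition)."""
        return cls(
            n_persons=n_persons, seed=seed,
            edge_rates={k: 0.0 for k in _DEFAULT_EDGE_RATES
                        if k not in ("multi_row_smoking", "stop_reason_present")},
            **kw,
        )


# ----------------------------------------------------------------- concepts

# (concept_id, name, domain, vocabulary, standard, code)
_CONCEPT_SEED: list[tuple[int, str, str, str, str, str]] = [
    (8507, "MALE", "Gender", "Gender", "S", "M"),
    (8532, "FEMALE", "Gender", "Gender", "S", "F"),
    (8521, "OTHER", "Gender", "Gender", "S", "OTHER"),
    (8551, "UNKNOWN", "Gender", "Gender", "S", "U"),
    (8527, "White", "Race", "Race", "S", "5"),
    (8516, "Black or African American", "Race", "Race", "S", "3"),
    (8515, "Asian", "Race", "Race", "S", "2"),
    (8657, "American Indian or Alaska Native", "Race", "Race", "S", "1"),
    (8557, "Native Hawaiian or Other Pacific Islander", "Race", "Race", "S", "4"),
    (38003563, "Hispanic or Latino", "Ethnicity", "Ethnicity", "S", "Hispanic"),
    (38003564, "Not Hispanic or Latino", "Ethnicity", "Ethnicity", "S", "Not Hispanic"),
    (9201, "Inpatient Visit", "Visit", "Visit", "S", "IP"),
    (9202, "Outpatient Visit", "Visit", "Visit", "S", "OP"),
    (9203, "Emergency Room Visit", "Visit", "Visit", "S", "ER"),
    (1000001, "Medicare", "Payer", "Payer", "S", "medicare"),
    (1000002, "Medicaid", "Payer", "Payer", "S", "medicaid"),
    (1000003, "Commercial insurance", "Payer", "Payer", "S", "commercial"),
    (1000004, "Self-pay", "Payer", "Payer", "S", "selfpay"),
    # drug type concepts
    (38000177, "Prescription written", "Type Concept", "Drug Type", "S", "OMOP4822240"),
    (38000175, "Prescription dispensed in pharmacy", "Type Concept", "Drug Type", "S", "OMOP4822241"),
    (38000180, "Inpatient administration", "Type Concept", "Drug Type", "S", "OMOP4822242"),
    (44787730, "Patient Self-Reported Medication", "Type Concept", "Drug Type", "S", "OMOP4822243"),
    # conditions: SNOMED standard + ICD10CM source pairs
    (320128, "Essential hypertension", "Condition", "SNOMED", "S", "59621000"),
    (2100001, "Essential (primary) hypertension", "Condition", "ICD10CM", "", "I10"),
    (201826, "Type 2 diabetes mellitus", "Condition", "SNOMED", "S", "44054006"),
    (2100002, "Type 2 diabetes mellitus without complications", "Condition", "ICD10CM", "", "E11.9"),
    (255573, "Chronic obstructive lung disease", "Condition", "SNOMED", "S", "13645005"),
    (2100003, "Chronic obstructive pulmonary disease, unspecified", "Condition", "ICD10CM", "", "J44.9"),
    (317009, "Asthma", "Condition", "SNOMED", "S", "195967001"),
    (2100004, "Unspecified asthma, uncomplicated", "Condition", "ICD10CM", "", "J45.909"),
    (432867, "Hyperlipidemia", "Condition", "SNOMED", "S", "55822004"),
    (2100005, "Hyperlipidemia, unspecified", "Condition", "ICD10CM", "", "E78.5"),
    # smoking status SNOMED codes (the six-code US Core subset)
    (2600001, "Smokes tobacco daily", "Observation", "SNOMED", "S", "449868002"),
    (2600002, "Occasional tobacco smoker", "Observation", "SNOMED", "S", "428041000124106"),
    (2600003, "Ex-smoker", "Observation", "SNOMED", "S", "8517006"),
    (2600004, "Never smoked tobacco", "Observation", "SNOMED", "S", "266919005"),
    (2600005, "Smoker", "Observation", "SNOMED", "S", "77176002"),
    (2600006, "Tobacco smoking consumption unknown", "Observation", "SNOMED", "S", "266927001"),
    # LOINC
    (2200001, "Tobacco smoking status NHIS", "Observation", "LOINC", "S", "72166-2"),
    (2200002, "Cholesterol [Mass/volume] in Serum or Plasma", "Measurement", "LOINC", "S", "2093-3"),
    (2200003, "Glucose [Mass/volume] in Serum or Plasma", "Measurement", "LOINC", "S", "2339-0"),
    (2200004, "Hemoglobin [Mass/volume] in Blood", "Measurement", "LOINC", "S", "718-7"),
    (2200005, "Highest level of education", "Observation", "LOINC", "S", "82589-3"),
    # units
    (8840, "milligram per deciliter", "Unit", "UCUM", "S", "mg/dL"),
    (8713, "gram per deciliter", "Unit", "UCUM", "S", "g/dL"),
    (8576, "milligram", "Unit", "UCUM", "S", "mg"),
    # drugs: RxNorm standard + NDC source
    (19019073, "lisinopril 10 MG Oral Tablet", "Drug", "RxNorm", "S", "314076"),
    (2300001, "lisinopril 10mg tablet NDC", "Drug", "NDC", "", "68180051301"),
    (1503297, "metformin hydrochloride 500 MG Oral Tablet", "Drug", "RxNorm", "S", "861007"),
    (2300002, "metformin 500mg tablet NDC", "Drug", "NDC", "", "00093104801"),
    (1539403, "simvastatin 20 MG Oral Tablet", "Drug", "RxNorm", "S", "312961"),
    (2300003, "simvastatin 20mg tablet NDC", "Drug", "NDC", "", "00006074031"),
    # vaccines
    (2400001, "Influenza, seasonal, injectable, preservative free", "Drug", "CVX", "S", "140"),
    (2400002, "COVID-19, mRNA, LNP-S, PF, 30 mcg/0.3 mL dose", "Drug", "CVX", "S", "208"),
    (2400003, "influenza virus vaccine, inactivated", "Drug", "RxNorm", "S", "253100"),
    # smoking survey question concepts
    (2500001, "Chewing tobacco use", "Observation", "OMOP Extension", "", "smoking-chew"),
    (2500002, "Cigarette packs per day", "Observation", "OMOP Extension", "", "smoking-ppd"),
    (2500003, "Cigarette use", "Observation", "OMOP Extension", "", "smoking-cig"),
    (2500004, "Cigar use", "Observation", "OMOP Extension", "", "smoking-cigar"),
    (2500005, "Pipe use", "Observation", "OMOP Extension", "", "smoking-pipe"),
    (2500006, "Snuff use", "Observation", "OMOP Extension", "", "smoking-snuff"),
    (2500007, "Tobacco use", "Observation", "OMOP Extension", "", "smoking-tobacco"),
    (2500008, "Tobacco use in years", "Observation", "OMOP Extension", "", "smoking-years"),
    (2500009, "Nicotine dependence, cigarettes, uncomplicated", "Condition", "ICD10CM", "", "F17.210"),
    (32817, "EHR", "Type Concept", "Type Concept", "S", "OMOP4976890"),
]

_CONDITION_PAIRS = [
    (320128, 2100001, "I10 - Essential (primary) hypertension"),
    (201826, 2100002, "E11.9 - Type 2 diabetes mellitus"),
    (255573, 2100003, "J44.9 - COPD"),
    (317009, 2100004, "J45.909 - Asthma"),
    (432867, 2100005, "E78.5 - Hyperlipidemia"),
]

_DRUGS = [  # (drug_concept_id, source_concept_id, source_value)
    (19019073, 2300001, "lisinopril 10mg tab"),
    (1503297, 2300002, "metformin 500mg tab"),
    (1539403, 2300003, "simvastatin 20mg tab"),
]

_LABS = [  # (concept_id, unit_concept_id, mean, sd)
    (2200002, 8840, 190.0, 35.0),
    (2200003, 8840, 100.0, 20.0),
    (2200004, 8713, 14.0, 1.5),
]

_PAYERS = [1000001, 1000002, 1000003, 1000004]
_PAYER_NAMES = {1000001: "Medicare", 1000002: "Medicaid",
                1000003: "Commercial", 1000004: "Self-pay"}

_SMOKING_QUESTION_CONCEPTS = {
    "Chew": 2500001, "CigarettePacksPerDay": 2500002, "Cigarettes": 2500003,
    "Cigars": 2500004, "Pipes": 2500005, "Snuff": 2500006,
    "TobaccoUse": 2500007, "TobaccoUseInYears": 2500008,
}
_DRUG_TYPE_CYCLE = (38000177, 38000180, 38000175, 38000177, 44787730)

_STATES = ["CO", "CA", "TX", "NY", "WA"]


def _iso(d: date) -> str:
    return d.isoformat()


class _Tables:
    def __init__(self) -> None:
        self.rows: dict[str, list[dict]] = {t: [] for t in EXPECTED_COLUMNS}

    def add(self, table: str, **values) -> None:
        self.rows[table].append(values)


def generate(config: SynthConfig, out_dir: Union[str, Path]) -> dict:
    """Write the 11 OMOP CSVs plus an edge-case manifest; returns the manifest."""
    rng = np.random.default_rng(config.seed)
    rates = config.edge_rates
    t = _Tables()
    manifest: dict = {
        "n_persons": config.n_persons,
        "seed": config.seed,
        "eligible_person_ids": [],
        "edges": {k: [] for k in rates},
    }

    for cid, name, domain, vocab, std, code in _CONCEPT_SEED:
        t.add("concept", concept_id=cid, concept_name=name, domain_id=domain,
              vocabulary_id=vocab, concept_class_id=domain,
              standard_concept=std, concept_code=code,
              valid_start_date="1970-01-01", valid_end_date="2099-12-31",
              invalid_reason="")
    for did, _, _ in _DRUGS:
        t.add("drug_strength", drug_concept_id=did, ingredient_concept_id=did,
              amount_value=10.0, amount_unit_concept_id=8576,
              numerator_value="", numerator_unit_concept_id="",
              denominator_value="", denominator_unit_concept_id="")

    start, end = config.date_range
    span_days = (end - start).days
    ids = {"visit": 0, "condition": 0, "payer": 0, "obs": 0, "meas": 0, "drug": 0}
    eligible: list[int] = []
    person_state: dict[int, dict] = {}

    for pid in range(1, config.n_persons + 1):
        flags = {k: bool(rng.random() < rates[k])
                 for k in ("missing_zip", "under_age", "pre_2017_only")}
        for k, v in flags.items():
            if v:
                manifest["edges"][k].append(pid)

        gender = 8507 if rng.random() < 0.5 else 8532
        race = int(rng.choice([8527, 8516, 8515], p=[0.7, 0.2, 0.1]))
        ethnicity = 38003563 if rng.random() < 0.15 else 38003564
        age = int(rng.integers(0, 2)) if flags["under_age"] else int(rng.integers(3, 90))
        birth = config.reference_date - timedelta(days=age * 365 + int(rng.integers(0, 365)))
        if flags["under_age"]:  # keep age strictly < 2 at the reference date
            birth = config.reference_date - timedelta(days=int(rng.integers(30, 700)))
        t.add("location", location_id=pid,
              address_1=f"{100 + pid} Main St", city="Denver",
              state="" if (flags["missing_zip"] and rng.random() < 0.3)
              else str(rng.choice(_STATES)),
              zip="8000" if flags["missing_zip"] else f"80{rng.integers(0, 1000):03d}",
              county="")
        t.add("person", person_id=pid, gender_concept_id=gender,
              year_of_birth=birth.year, month_of_birth=birth.month,
              day_of_birth=birth.day, birth_datetime=f"{_iso(birth)}T00:00:00",
              race_concept_id=race, ethnicity_concept_id=ethnicity,
              location_id=pid, provider_id="", care_site_id="",
              person_source_value=f"MRN{pid:06d}",
              gender_source_value="M" if gender == 8507 else "F",
              race_source_value="", ethnicity_source_value="")
        deceased = rng.random() < 0.03
        if deceased:
            dd = start + timedelta(days=int(rng.integers(0, span_days)))
            t.add("death", person_id=pid, death_date=_iso(dd),
                  death_datetime=f"{_iso(dd)}T00:00:00",
                  death_type_concept_id=32817, cause_concept_id="")

        n_visits = 1 + int(rng.poisson(2))
        visit_ids = []
        first_visit_date = None
        for _ in range(n_visits):
            ids["visit"] += 1
            vid = ids["visit"]
            if flags["pre_2017_only"]:
                vdate = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 720)))
            else:
                vdate = start + timedelta(days=int(rng.integers(0, span_days)))
            vclass = int(rng.choice([9201, 9202, 9203], p=[0.15, 0.7, 0.15]))
            has_end = rng.random() < 0.9
            vend = vdate + timedelta(days=int(rng.integers(0, 5))) if has_end else None
            t.add("visit_occurrence", visit_occurrence_id=vid, person_id=pid,
                  visit_concept_id=vclass, visit_start_date=_iso(vdate),
                  visit_start_datetime=f"{_iso(vdate)}T08:00:00",
                  visit_end_date=_iso(vend) if vend else "",
                  visit_end_datetime=f"{_iso(vend)}T17:00:00" if vend else "",
                  visit_type_concept_id=32817, provider_id="", care_site_id="",
                  visit_source_value=f"visit-{vid}")
            visit_ids.append((vid, vdate))
            if first_visit_date is None:
                first_visit_date = vdate

        is_eligible = (
            not flags["under_age"] and not flags["missing_zip"]
            and not flags["pre_2017_only"] and age >= 2
        )
        if is_eligible:
            eligible.append(pid)
        person_state[pid] = {"visits": visit_ids, "gender": gender}

        # conditions
        for vid, vdate in visit_ids:
            for _ in range(int(rng.poisson(0.8))):
                ids["condition"] += 1
                std_c, src_c, src_v = _CONDITION_PAIRS[int(rng.integers(0, len(_CONDITION_PAIRS)))]
                resolved = rng.random() < 0.3
                t.add("condition_occurrence",
                      condition_occurrence_id=ids["condition"], person_id=pid,
                      condition_concept_id=std_c,
                      condition_start_date=_iso(vdate),
                      condition_start_datetime=f"{_iso(vdate)}T08:00:00",
                      condition_end_date=_iso(vdate + timedelta(days=30)) if resolved else "",
                      condition_end_datetime="",
                      condition_type_concept_id=32817, stop_reason="",
                      provider_id="", visit_occurrence_id=vid,
                      condition_source_value=src_v,
                      condition_source_concept_id=src_c,
                      condition_status_concept_id="")

        # coverage periods
        n_periods = 1
        overlap = rng.random() < rates["overlapping_coverage"]
        if overlap:
            n_periods = 2
            manifest["edges"]["overlapping_coverage"].append(pid)
        base_start = date(2017, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        for i in range(n_periods):
            ids["payer"] += 1
            payer = _PAYERS[int(rng.integers(0, len(_PAYERS)))]
            pstart = base_start if i == 0 else base_start + timedelta(days=int(rng.integers(0, 180)))
            pend = pstart + timedelta(days=int(rng.integers(365, 2000)))
            inverted = rng.random() < rates["inverted_period"]
            if inverted:
                pstart, pend = pend, pstart
                manifest["edges"]["inverted_period"].append(ids["payer"])
            t.add("payer_plan_period", payer_plan_period_id=ids["payer"],
                  person_id=pid, payer_plan_period_start_date=_iso(pstart),
                  payer_plan_period_end_date=_iso(pend),
                  payer_concept_id=payer,
                  payer_source_value=_PAYER_NAMES[payer],
                  plan_concept_id="", plan_source_value="")

        # smoking survey on the first visit
        if rng.random() < 0.8 and visit_ids:
            vid, vdate = visit_ids[0]
            tobacco = str(rng.choice(["Yes", "No", "Quit"], p=[0.3, 0.5, 0.2]))
            responses = [("TobaccoUse", tobacco)]
            if rng.random() < rates["multi_row_smoking"]:
                responses.append(("Cigarettes",
                                  str(rng.choice(["Yes", "No", "Some days"]))))
                extra = ["Chew", "Cigars", "Pipes", "Snuff",
                         "CigarettePacksPerDay", "TobaccoUseInYears"]
                n_extra = int(rng.integers(0, min(len(extra),
                              config.smoking_rows_per_survey_max - 2) + 1))
                for q in extra[:n_extra]:
                    a = "<20" if q == "CigarettePacksPerDay" else (
                        "+" if q == "TobaccoUseInYears" else "No")
                    responses.append((q, a))
            for q, a in responses:
                ids["obs"] += 1
                t.add("observation", observation_id=ids["obs"], person_id=pid,
                      observation_concept_id=_SMOKING_QUESTION_CONCEPTS[q],
                      observation_date=_iso(vdate),
                      observation_datetime=f"{_iso(vdate)}T09:00:00",
                      observation_type_concept_id=32817, value_as_number="",
                      value_as_string=a, value_as_concept_id="",
                      qualifier_concept_id="", unit_concept_id="",
                      provider_id="", visit_occurrence_id=vid,
                      observation_source_value=q,
                      observation_source_concept_id="", unit_source_value="")

        # a non-smoking social-history observation
        if rng.random() < 0.5 and visit_ids:
            vid, vdate = visit_ids[0]
            ids["obs"] += 1
            t.add("observation", observation_id=ids["obs"], person_id=pid,
                  observation_concept_id=2200005, observation_date=_iso(vdate),
                  observation_datetime=f"{_iso(vdate)}T09:30:00",
                  observation_type_concept_id=32817, value_as_number="",
                  value_as_string=str(rng.choice(
                      ["High school diploma", "Bachelor's degree", "Associate degree"])),
                  value_as_concept_id="", qualifier_concept_id="",
                  unit_concept_id="", provider_id="", visit_occurrence_id=vid,
                  observation_source_value="EducationLevel",
                  observation_source_concept_id="", unit_source_value="")

        # labs
        for vid, vdate in visit_ids:
            for _ in range(int(rng.poisson(1.0))):
                ids["meas"] += 1
                lab, unit, mean, sd = _LABS[int(rng.integers(0, len(_LABS)))]
                t.add("measurement", measurement_id=ids["meas"], person_id=pid,
                      measurement_concept_id=lab, measurement_date=_iso(vdate),
                      measurement_datetime=f"{_iso(vdate)}T10:00:00",
                      measurement_type_concept_id=32817, operator_concept_id="",
                      value_as_number=round(float(rng.normal(mean, sd)), 1),
                      value_as_concept_id="", unit_concept_id=unit,
                      range_low="", range_high="", provider_id="",
                      visit_occurrence_id=vid,
                      measurement_source_value="", measurement_source_concept_id="",
                      unit_source_value="")

        # drug exposures
        n_drugs = int(rng.poisson(1.5))
        for _ in range(n_drugs):
            _add_drug_row(t, ids, rng, rates, manifest, pid, visit_ids,
                          forced_type=None)
        # vaccines
        if rng.random() < 0.3 and visit_ids:
            non_cvx = rng.random() < rates["non_cvx_vaccine"]
            if non_cvx:
                manifest["edges"]["non_cvx_vaccine"].append(pid)
            _add_vaccine_row(t, ids, rng, pid, visit_ids, non_cvx=non_cvx)

    # structural guarantee: every route at least once, on the first
    # cohort-eligible person (skipped only when no person is eligible)
    if eligible:
        pid = eligible[0]
        visit_ids = person_state[pid]["visits"]
        for dtype in (38000177, 38000180, 38000175, 44787730):
            _add_drug_row(t, ids, rng, rates, manifest, pid, visit_ids,
                          forced_type=dtype, forced_present_requester=True)
        _add_vaccine_row(t, ids, rng, pid, visit_ids, non_cvx=False)

    manifest["eligible_person_ids"] = eligible
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for table, columns in EXPECTED_COLUMNS.items():
        with open(out_dir / f"{table}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(columns))
            writer.writeheader()
            for row in t.rows[table]:
                writer.writerow({c: row.get(c, "") for c in columns})
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    return manifest


def _add_drug_row(t, ids, rng, rates, manifest, pid, visit_ids,
                  forced_type=None, forced_present_requester=False) -> None:
    ids["drug"] += 1
    did = ids["drug"]
    drug, src, src_v = _DRUGS[int(rng.integers(0, len(_DRUGS)))]
    dtype = forced_type if forced_type is not None else (
        _DRUG_TYPE_CYCLE[(did - 1) % len(_DRUG_TYPE_CYCLE)]
    )
    vid, vdate = visit_ids[int(rng.integers(0, len(visit_ids)))]
    has_end = rng.random() < 0.7
    missing_req = (not forced_present_requester
                   and rng.random() < rates["missing_requester"])
    if missing_req:
        manifest["edges"]["missing_requester"].append(did)
    stop = rng.random() < rates["stop_reason_present"]
    has_qty = rng.random() < 0.7
    t.add("drug_exposure", drug_exposure_id=did, person_id=pid,
          drug_concept_id=drug,
          drug_exposure_start_date=_iso(vdate),
          drug_exposure_start_datetime=f"{_iso(vdate)}T11:00:00",
          drug_exposure_end_date=_iso(vdate + timedelta(days=30)) if has_end else "",
          drug_exposure_end_datetime="", verbatim_end_date="",
          drug_type_concept_id=dtype,
          stop_reason="completed course" if stop else "",
          refills="", quantity=30.0 if has_qty else "", days_supply=30 if has_qty else "",
          sig="take one tablet daily", route_concept_id="", lot_number="",
          provider_id="" if missing_req else 100 + (pid % 20),
          visit_occurrence_id=vid, drug_source_value=src_v,
          drug_source_concept_id=src, route_source_value="",
          dose_unit_source_value="")


def _add_vaccine_row(t, ids, rng, pid, visit_ids, non_cvx: bool) -> None:
    ids["drug"] += 1
    did = ids["drug"]
    vid, vdate = visit_ids[int(rng.integers(0, len(visit_ids)))]
    drug = 2400003 if non_cvx else int(rng.choice([2400001, 2400002]))
    t.add("drug_exposure", drug_exposure_id=did, person_id=pid,
          drug_concept_id=drug,
          drug_exposure_start_date=_iso(vdate),
          drug_exposure_start_datetime=f"{_iso(vdate)}T11:30:00",
          drug_exposure_end_date=_iso(vdate), drug_exposure_end_datetime="",
          verbatim_end_date="", drug_type_concept_id=38000180, stop_reason="",
          refills="", quantity="", days_supply="", sig="", route_concept_id="",
          lot_number="", provider_id=100 + (pid % 20), visit_occurrence_id=vid,
          drug_source_value="flu vaccine" if non_cvx else "seasonal vaccine",
          drug_source_concept_id="", route_source_value="",
          dose_unit_source_value="")


# ------------------------------------------------------------------ fixtures

def worked_example_fixture() -> dict[str, OmopJsonDocument]:
    """Golden-test documents: the printed smoking survey and a condition doc.

    The smoking document carries the nine survey OBSERVATION rows whose
    concatenation is exactly :data:`WORKED_SMOKING_STRING`; the condition
    document is a two-row single-key document in the published OMOP JSON
    shape.
    """
    components = [
        ("Chew", "No", 2500001),
        ("CigarettePacksPerDay", "<20", 2500002),
        ("Cigarettes", "No", 2500003),
        ("Cigars", "No", 2500004),
        ("Nicotine dependence, cigarettes, uncomplicated", None, 2500009),
        ("Pipes", "No", 2500005),
        ("Snuff", "No", 2500006),
        ("TobaccoUse", "Yes", 2500007),
        ("TobaccoUseInYears", "+", 2500008),
    ]
    obs_rows = []
    for i, (question, answer, concept) in enumerate(components, start=1):
        obs_rows.append({
            "observation_id": i, "person_id": 1,
            "observation_concept_id": concept,
            "observation_date": "2019-04-01",
            "observation_datetime": "2019-04-01T09:00:00",
            "observation_type_concept_id": 32817,
            "value_as_number": None,
            "value_as_string": answer,
            "value_as_concept_id": None, "qualifier_concept_id": None,
            "unit_concept_id": None, "provider_id": None,
            "visit_occurrence_id": 1,
            "observation_source_value": question,
            "observation_source_concept_id": None, "unit_source_value": None,
        })
    smoking_doc = OmopJsonDocument(table="observation", rows=obs_rows, index=0)

    condition_rows = [
        {
            "condition_occurrence_id": 11, "person_id": 1,
            "condition_concept_id": 320128,
            "condition_start_date": "2019-04-01",
            "condition_end_date": None,
            "condition_type_concept_id": 32817,
            "visit_occurrence_id": 1,
            "condition_source_value": "I10 - Essential (primary) hypertension",
            "condition_source_concept_id": 2100001,
        },
        {
            "condition_occurrence_id": 12, "person_id": 1,
            "condition_concept_id": 201826,
            "condition_start_date": "2019-05-01",
            "condition_end_date": "2019-06-01",
            "condition_type_concept_id": 32817,
            "visit_occurrence_id": 1,
            "condition_source_value": "E11.9 - Type 2 diabetes mellitus",
            "condition_source_concept_id": 2100002,
        },
    ]
    condition_doc = OmopJsonDocument(table="condition_occurrence",
                                     rows=condition_rows, index=0)
    return {"smoking": smoking_doc, "condition": condition_doc}
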
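"""FHIR resource builders: field rules, dual coding, routing, determinism."""

from __future__ import annotations

import json
from collections import Counter

import pytest

from omopfhir.omop_store import ExtractionConfig
from omopfhir.synthgen import worked_example_fixture
from omopfhir.transform import (
    ResourceTransformer,
    local_ref,
    registry_fhir_types,
    registry_omop_tables,
)


def person_row(**kw):
    base = dict(person_id=1, gender_concept_id=8507, year_of_birth=1980,
                month_of_birth=2, day_of_birth=3,
                birth_datetime="1980-02-03T00:00:00",
                race_concept_id=8527, ethnicity_concept_id=38003564,
                death_date=None, death_datetime=None,
                zip="80045", state="CO", city="Denver")
    base.update(kw)
    return base


def drug_row(**kw):
    base = dict(drug_exposure_id=10, person_id=1, drug_concept_id=19019073,
                drug_code="314076", drug_name="lisinopril 10 MG Oral Tablet",
                drug_vocabulary="RxNorm",
                drug_source_concept_id=2300001, drug_source_code="68180051301",
                drug_source_name="lisinopril 10mg tablet NDC",
                drug_source_vocabulary="NDC",
                drug_exposure_start_date="2020-01-05",
                drug_exposure_end_date=None, drug_type_concept_id=38000177,
                stop_reason=None, quantity=None, sig=None,
                provider_id=None, visit_provider_id=None,
                visit_occurrence_id=3, amount_unit_concept_id=None)
    base.update(kw)
    return base


class TestRegistry:
    def test_eleven_omop_tables_feed_ten_fhir_types(self):
        assert len(registry_omop_tables()) == 11
        assert len(registry_fhir_types()) == 10


class TestPatient:
    def test_death_date_becomes_deceased_datetime(self, transformer):
        r = transformer.build_patient(person_row(death_date="2020-01-02"))
        assert r.body["deceasedDateTime"].startswith("2020-01-02")

    def test_gender_translated_through_concept_map(self, transformer):
        r = transformer.build_patient(person_row(gender_concept_id=8532))
        assert r.body["gender"] == "female"

    def test_unmatched_race_extension_omitted(self, transformer, caplog):
        r = transformer.build_patient(person_row(race_concept_id=99999))
        urls = [e["url"] for e in r.body.get("extension", [])]
        assert not any(u.endswith("us-core-race") for u in urls)
        # ethnicity and birthsex still present
        assert any(u.endswith("us-core-ethnicity") for u in urls)

    def test_missing_person_id_skips_row(self, transformer):
        assert transformer.build_patient(person_row(person_id=None)) is None

    def test_address_carries_zip_and_state(self, transformer):
        r = transformer.build_patient(person_row())
        assert r.body["address"][0]["postalCode"] == "80045"
        assert r.body["address"][0]["state"] == "CO"


class TestEncounter:
    def _visit(self, **kw):
        base = dict(visit_occurrence_id=5, person_id=1, visit_concept_id=9202,
                    visit_start_date="2018-03-01", visit_end_date="2018-03-01")
        base.update(kw)
        return base

    def test_outpatient_visit_is_finished_ambulatory(self, transformer):
        r = transformer.build_encounter(self._visit())
        assert r.body["status"] == "finished"
        assert r.body["class"]["code"] == "AMB"
        assert r.body["period"] == {"start": "2018-03-01", "end": "2018-03-01"}

    def test_open_visit_is_in_progress(self, transformer):
        r = transformer.build_encounter(self._visit(visit_end_date=None))
        assert r.body["status"] == "in-progress"
        assert "end" not in r.body["period"]

    def test_one_encounter_per_visit_row(self, transformer):
        rows = [self._visit(visit_occurrence_id=i) for i in range(1, 4)]
        resources = transformer.transform_rows("visit_occurrence", rows)
        assert len(resources) == 3


class TestCondition:
    def test_dual_coding_standard_first(self, transformer):
        fixture = worked_example_fixture()["condition"]
        # shaped rows carry resolved concept fields; emulate the store shaping
        row = dict(fixture.rows[0], condition_code="59621000",
                   condition_name="Essential hypertension",
                   condition_vocabulary="SNOMED",
                   condition_source_code="I10",
                   condition_source_name="Essential (primary) hypertension",
                   condition_source_vocabulary="ICD10CM")
        r = transformer.build_condition(row)
        codings = r.body["code"]["coding"]
        assert len(codings) == 2
        assert codings[0]["system"] == "http://snomed.info/sct"
        assert codings[1]["system"] == "http://hl7.org/fhir/sid/icd-10-cm"

    def test_standard_only_yields_one_coding(self, transformer):
        row = dict(condition_occurrence_id=1, person_id=1,
                   condition_code="59621000", condition_name="Essential hypertension",
                   condition_vocabulary="SNOMED", condition_start_date="2020-01-01")
        r = transformer.build_condition(row)
        assert len(r.body["code"]["coding"]) == 1

    def test_unresolvable_codes_fall_back_to_text(self, transformer):
        row = dict(condition_occurrence_id=1, person_id=1,
                   condition_source_value="mystery dx",
                   condition_start_date="2020-01-01")
        r = transformer.build_condition(row)
        assert r.body["code"] == {"text": "mystery dx"}

    def test_clinical_status_follows_end_date(self, transformer):
        open_row = dict(condition_occurrence_id=1, person_id=1,
                        condition_source_value="x", condition_start_date="2020-01-01")
        closed = dict(open_row, condition_occurrence_id=2,
                      condition_end_date="2020-06-01")
        assert transformer.build_condition(open_row).body[
            "clinicalStatus"]["coding"][0]["code"] == "active"
        r = transformer.build_condition(closed)
        assert r.body["clinicalStatus"]["coding"][0]["code"] == "resolved"
        assert r.body["abatementDateTime"] == "2020-06-01"

    def test_document_rows_map_one_to_one(self, transformer):
        doc = worked_example_fixture()["condition"]
        assert len(transformer.transform_rows(doc.table, doc.rows)) == len(doc.rows)


class TestCoverage:
    def _row(self, **kw):
        base = dict(payer_plan_period_id=7, person_id=1,
                    payer_plan_period_start_date="2018-01-01",
                    payer_plan_period_end_date="2018-12-31",
                    payer_concept_id=1000002, payer_source_value="Medicaid")
        base.update(kw)
        return base

    def test_period_and_mapped_payer_type(self, transformer):
        r = transformer.build_coverage(self._row())
        assert r.body["period"] == {"start": "2018-01-01", "end": "2018-12-31"}
        assert r.body["type"]["coding"][0]["code"] == "MEDICAID"

    def test_open_ended_period_omits_end(self, transformer):
        r = transformer.build_coverage(self._row(payer_plan_period_end_date=None))
        assert "end" not in r.body["period"]

    def test_inverted_period_still_emitted(self, transformer):
        r = transformer.build_coverage(self._row(
            payer_plan_period_start_date="2019-01-01",
            payer_plan_period_end_date="2018-01-01"))
        assert r.body["period"]["start"] == "2019-01-01"  # kept as-is


class TestMedicationRules:
    """status x requester x doseQuantity truth table."""

    @pytest.mark.parametrize("stop_reason,expected", [
        ("completed course", "stopped"), (None, "unknown")])
    def test_request_status_from_stop_reason(self, transformer, stop_reason, expected):
        assert transformer.infer_medication_status(
            drug_row(stop_reason=stop_reason), "request") == expected

    @pytest.mark.parametrize("family", ["administration", "dispense"])
    @pytest.mark.parametrize("end,expected", [
        ("2020-02-01", "completed"), (None, "in-progress")])
    def test_event_status_from_end_date(self, transformer, family, end, expected):
        assert transformer.infer_medication_status(
            drug_row(drug_exposure_end_date=end), family) == expected

    def test_requester_from_drug_provider(self, transformer):
        req = transformer.resolve_requester(drug_row(provider_id=42))
        assert req["reference"] == "Practitioner/42"

    def test_requester_absent_when_no_provider(self, transformer):
        assert transformer.resolve_requester(drug_row()) is None
        event, _ = transformer.build_medication_family(drug_row(), "request")
        assert "requester" not in event.body  # still emitted, knowingly short

    def test_visit_provider_wins_over_drug_provider(self, transformer):
        req = transformer.resolve_requester(
            drug_row(provider_id=42, visit_provider_id=7))
        assert req["reference"] == "Practitioner/7"

    def test_dose_quantity_only_when_quantity_present(self, transformer):
        event, _ = transformer.build_medication_family(drug_row(), "request")
        assert "dosageInstruction" not in json.dumps(event.body) or not any(
            "doseQuantity" in json.dumps(d) for d in event.body.get("dosageInstruction", []))
        event2, _ = transformer.build_medication_family(
            drug_row(quantity=30.0), "request")
        dq = event2.body["dosageInstruction"][0]["doseAndRate"][0]["doseQuantity"]
        assert dq["value"] == 30.0


class TestMedicationFamilyAndRouting:
    def test_cvx_routes_to_immunization(self, transformer):
        row = drug_row(drug_vocabulary="CVX", drug_code="140",
                       drug_name="Influenza, seasonal, injectable, preservative free")
        assert transformer.route_drug_exposure(row) == "immunization"
        imm = transformer.build_immunization(row)
        assert imm.body["vaccineCode"]["coding"][0]["system"] == "http://hl7.org/fhir/sid/cvx"
        assert imm.body["status"] == "completed"

    @pytest.mark.parametrize("dtype,expected", [
        (38000177, "request"), (38000180, "administration"), (38000175, "dispense")])
    def test_drug_type_routing_table(self, transformer, dtype, expected):
        assert transformer.route_drug_exposure(
            drug_row(drug_type_concept_id=dtype)) == expected

    def test_patient_reported_and_unknown_types_skip(self, transformer):
        assert transformer.route_drug_exposure(
            drug_row(drug_type_concept_id=44787730)) is None
        assert transformer.route_drug_exposure(
            drug_row(drug_type_concept_id=123456)) is None

    def test_non_cvx_row_rejected_by_immunization_builder(self, transformer):
        with pytest.raises(ValueError, match="not routed"):
            transformer.build_immunization(drug_row())

    def test_medication_carries_rxnorm_and_ndc_dual_coding(self, transformer):
        _, medication = transformer.build_medication_family(drug_row(), "request")
        systems = [c["system"] for c in medication.body["code"]["coding"]]
        assert systems == [
            "http://www.nlm.nih.gov/research/umls/rxnorm",
            "http://hl7.org/fhir/sid/ndc",
        ]

    def test_medication_deduplicated_per_drug_concept(self, transformer):
        e1, m1 = transformer.build_medication_family(drug_row(drug_exposure_id=1), "request")
        e2, m2 = transformer.build_medication_family(drug_row(drug_exposure_id=2), "dispense")
        assert m1 is not None and m2 is None
        assert e1.body["medicationReference"] == e2.body["medicationReference"]


class TestBundles:
    def test_entry_count_matches_resources(self, transformer):
        rows = [person_row(person_id=i) for i in range(1, 6)]
        bundle = transformer.wrap_bundle(
            transformer.transform_rows("person", rows))
        assert len(bundle.entries) == 5
        assert transformer.wrap_bundle([]).entries == []

    def test_full_urls_unique_and_deterministic(self, transformer):
        assert local_ref("Patient", "person", 1) == local_ref("Patient", "person", 1)
        assert local_ref("Patient", "person", 1) != local_ref("Patient", "person", 2)

    def test_same_input_yields_byte_identical_bundle_json(self, terminology):
        doc = worked_example_fixture()["condition"]
        a = ResourceTransformer(terminology).transform_document(doc)
        b = ResourceTransformer(terminology).transform_document(doc)
        assert json.dumps(a.to_fhir()) == json.dumps(b.to_fhir())


class TestChunkInvariance:
    @pytest.mark.parametrize("chunk_size", [1, 7, 1000])
    def test_resource_multiset_independent_of_chunk_size(
            self, store, cohort, terminology, chunk_size):
        baseline = self._multiset(store, cohort, terminology, 10_000)
        assert self._multiset(store, cohort, terminology, chunk_size) == baseline

    @staticmethod
    def _multiset(store, cohort, terminology, chunk_size):
        transformer = ResourceTransformer(terminology)
        out = Counter()
        for table in ExtractionConfig().tables:
            for doc in store.extract_table_json(
                    table, ExtractionConfig(chunk_size=chunk_size), cohort):
                for r in transformer.transform_rows(doc.table, doc.rows):
                    out[json.dumps(r.body, sort_keys=True)] += 1
        return out


class TestObservationDispatch:
    def test_three_profile_variants(self, transformer, store, cohort):
        profiles = set()
        for table in ("observation", "measurement"):
            for row in store.shaped_table(table, cohort):
                profiles.add(transformer.observation_profile(row, table))
        assert profiles == {"laboratory", "smoking", "non-smoking"}

    def test_lab_observation_carries_value_quantity(self, transformer, store, cohort):
        row = next(r for r in store.shaped_table("measurement", cohort)
                   if r.get("value_as_number") is not None)
        r = transformer.build_observation(row, "laboratory")
        assert r.body["category"][0]["coding"][0]["code"] == "laboratory"
        assert r.body["valueQuantity"]["value"] == row["value_as_number"]
        assert r.body["code"]["coding"][0]["system"] == "http://loinc.org"

    def test_smoking_observation_retains_full_text(self, transformer, store, cohort):
        row = next(r for r in store.shaped_table("observation", cohort)
                   if r.get("is_smoking_aggregate"))
        r = transformer.build_observation(row, "smoking")
        vcc = r.body["valueCodeableConcept"]
        assert vcc["text"] == row["observation_source_value"]
        assert vcc["coding"][0]["system"] == "http://snomed.info/sct"
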
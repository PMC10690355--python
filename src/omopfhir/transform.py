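"""OMOP JSON to US Core-style FHIR R4 resource builders.

Each builder consumes one shaped OMOP row (the extraction stage has already
joined in everything the resource needs — resolved concept codes, location,
death, drug strength, visit provider) and returns a :class:`FhirResource`
whose body is a plain JSON tree.  A document's resources are wrapped into a
single collection Bundle.

Resource identity is deterministic: every resource gets a ``urn:uuid``
local reference derived from (resource type, source table, primary key) via
UUIDv5, so re-running a transformation — at any chunk size — produces
byte-identical Bundles, and cross-resource references can be rewired
reproducibly at import time.

Dual coding policy: the US Core-required standard coding (SNOMED for
conditions, RxNorm for drugs) is listed first, followed by the nonstandard
EHR source coding (ICD-9/10-CM, NDC) when the source concept resolves.
Unmappable fields are left blank (with a logged warning) rather than
filled with fabricated values, even where that makes the resource
knowingly non-conformant; such resources still flow through the pipeline.
"""

from __future__ import annotations

import logging
import uuid
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .omop_store import OmopJsonDocument
from .smoking import SmokingResponse, SmokingRules, allowed_smoking_codes
from .terminology import (
    CodeableConcept,
    Coding,
    TerminologyService,
    Unmatched,
)

log = logging.getLogger(__name__)

__all__ = [
    "FhirResource",
    "Bundle",
    "ResourceTransformer",
    "MAPPING_REGISTRY",
    "registry_omop_tables",
    "registry_fhir_types",
    "local_ref",
    "DEFAULT_DRUG_TYPE_ROUTING",
]

#: UUIDv5 namespace for deterministic local references.
_NAMESPACE = uuid.uuid5(uuid.NAMESPACE_URL, "urn:omopfhir:local-ref")

#: Surveillance data domain -> (FHIR resource types, OMOP tables used).
#: Exactly 11 distinct OMOP tables feed exactly 10 FHIR resource types.
MAPPING_REGISTRY: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Patient": (("Patient",), ("person", "location", "death", "concept")),
    "Encounter": (("Encounter",), ("visit_occurrence", "concept")),
    "Condition": (("Condition",), ("condition_occurrence", "concept")),
    "Coverage": (("Coverage",), ("payer_plan_period", "concept")),
    "Lab Result": (("Observation",), ("measurement", "concept")),
    "Social History": (("Observation",), ("observation", "concept")),
    "Prescription": (
        ("MedicationRequest", "MedicationAdministration", "MedicationDispense", "Medication"),
        ("drug_exposure", "drug_strength", "concept"),
    ),
    "Immunization": (("Immunization",), ("drug_exposure", "drug_strength", "concept")),
}


def registry_omop_tables() -> set[str]:
    return {t for _, tables in MAPPING_REGISTRY.values() for t in tables}


def registry_fhir_types() -> set[str]:
    return {r for types, _ in MAPPING_REGISTRY.values() for r in types}


#: drug_type_concept_id -> medication event family.  "skip" drops the row
#: (patient-reported medications are future work, not an event resource).
DEFAULT_DRUG_TYPE_ROUTING: dict[int, str] = {
    38000177: "request",         # Prescription written
    38000175: "dispense",        # Prescription dispensed in pharmacy
    38000180: "administration",  # Inpatient administration
    44787730: "skip",            # Patient self-reported medication
}

#: Fixed code of the aggregated smoking-status Observation.
SMOKING_STATUS_CODING = Coding(
    system="http://loinc.org", code="72166-2", display="Tobacco smoking status NHIS"
)

_EXT_RACE = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-race"
_EXT_ETHNICITY = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity"
_EXT_BIRTHSEX = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-birthsex"

#: ConceptMap ids every transformation run requires.
REQUIRED_MAPS = (
    "gender", "birthsex", "race", "ethnicity",
    "visit-class", "coverage-type", "smoking-status",
)


@dataclass
class FhirResource:
    resource_type: str
    body: dict
    local_ref: str

    def __post_init__(self) -> None:
        if self.body.get("resourceType") != self.resource_type:
            raise ValueError("body.resourceType does not match resource_type")


@dataclass
class Bundle:
    type: str
    entries: list[dict] = field(default_factory=list)
    id: Optional[str] = None
    extension: Optional[list[dict]] = None

    def to_fhir(self) -> dict:
        body: dict = {"resourceType": "Bundle"}
        if self.id:
            body["id"] = self.id
        if self.extension:
            body["extension"] = self.extension
        body["type"] = self.type
        body["entry"] = self.entries
        return body


def local_ref(resource_type: str, table: str, primary_key) -> str:
    """Deterministic urn:uuid for (resource type, source table, primary key)."""
    return "urn:uuid:" + str(
        uuid.uuid5(_NAMESPACE, f"{resource_type}|{table}|{primary_key}")
    )


def _ref(target: str) -> dict:
    return {"reference": target}


def _patient_ref(person_id) -> dict:
    return _ref(local_ref("Patient", "person", person_id))


def _encounter_ref(visit_id) -> Optional[dict]:
    if visit_id in (None, ""):
        return None
    return _ref(local_ref("Encounter", "visit_occurrence", visit_id))


class ResourceTransformer:
    """Builds FHIR resources from shaped OMOP JSON rows.

    Medication resources are deduplicated per distinct drug_concept_id for
    the lifetime of the transformer (one pipeline run).
    """

    def __init__(
        self,
        terminology: TerminologyService,
        smoking_rules: Optional[SmokingRules] = None,
        drug_type_routing: Optional[dict[int, str]] = None,
        requester_precedence: Sequence[str] = ("visit_provider_id", "provider_id"),
    ):
        terminology.require_maps(REQUIRED_MAPS)
        n_smoking = len(allowed_smoking_codes(terminology))
        if n_smoking != 6:
            raise ValueError(f"expected 6 allowed smoking codes, got {n_smoking}")
        self.terminology = terminology
        self.smoking_rules = smoking_rules or SmokingRules.load()
        self.routing = dict(drug_type_routing or DEFAULT_DRUG_TYPE_ROUTING)
        self.requester_precedence = tuple(requester_precedence)
        self._medications_emitted: set[int] = set()

    # ------------------------------------------------------------------ utils

    def _row_coding(self, row: dict, base: str) -> Optional[Coding]:
        """Coding from the resolved ``<base>_code/_name/_vocabulary`` fields."""
        code = row.get(f"{base}_code")
        if code in (None, ""):
            return None
        vocab = row.get(f"{base}_vocabulary") or ""
        return Coding(
            system=self.terminology.system_for(vocab),
            code=str(code),
            display=row.get(f"{base}_name"),
        )

    def _translate_coding(self, map_id: str, source_code) -> Optional[Coding]:
        if source_code in (None, ""):
            return None
        result = self.terminology.translate(map_id, source_code)
        if isinstance(result, Unmatched) or not result:
            log.warning("unmatched translation: map=%s code=%s", map_id, source_code)
            return None
        return result[0]

    # --------------------------------------------------------------- builders

    def build_patient(self, row: dict) -> Optional[FhirResource]:
        pid = row.get("person_id")
        if pid in (None, ""):
            log.warning("person row without person_id skipped")
            return None
        body: dict = {"resourceType": "Patient"}
        extensions = []
        race = self._translate_coding("race", row.get("race_concept_id"))
        if race is not None:
            extensions.append({
                "url": _EXT_RACE,
                "extension": [
                    {"url": "ombCategory", "valueCoding": race.to_fhir()},
                    {"url": "text", "valueString": race.display or race.code},
                ],
            })
        ethnicity = self._translate_coding("ethnicity", row.get("ethnicity_concept_id"))
        if ethnicity is not None:
            extensions.append({
                "url": _EXT_ETHNICITY,
                "extension": [
                    {"url": "ombCategory", "valueCoding": ethnicity.to_fhir()},
                    {"url": "text", "valueString": ethnicity.display or ethnicity.code},
                ],
            })
        birthsex = self._translate_coding("birthsex", row.get("gender_concept_id"))
        if birthsex is not None:
            extensions.append({"url": _EXT_BIRTHSEX, "valueCode": birthsex.code})
        if extensions:
            body["extension"] = extensions
        body["identifier"] = [{"system": "urn:omopfhir:person-id", "value": str(pid)}]
        gender = self._translate_coding("gender", row.get("gender_concept_id"))
        if gender is not None:
            body["gender"] = gender.code
        birth = self._birth_date_str(row)
        if birth:
            body["birthDate"] = birth
        if row.get("death_date") or row.get("death_datetime"):
            body["deceasedDateTime"] = row.get("death_datetime") or row.get("death_date")
        address = {}
        if row.get("zip"):
            address["postalCode"] = row["zip"]
        if row.get("state"):
            address["state"] = row["state"]
        if row.get("city"):
            address["city"] = row["city"]
        if address:
            body["address"] = [address]
        return FhirResource("Patient", body, local_ref("Patient", "person", pid))

    @staticmethod
    def _birth_date_str(row: dict) -> Optional[str]:
        bd = row.get("birth_datetime")
        if bd:
            return str(bd)[:10]
        y = row.get("year_of_birth")
        if y in (None, ""):
            return None
        m = int(row.get("month_of_birth") or 1)
        d = int(row.get("day_of_birth") or 1)
        return f"{int(y):04d}-{m:02d}-{d:02d}"

    def build_encounter(self, row: dict) -> FhirResource:
        vid = row["visit_occurrence_id"]
        body: dict = {"resourceType": "Encounter"}
        body["status"] = "finished" if row.get("visit_end_date") else "in-progress"
        klass = self._translate_coding("visit-class", row.get("visit_concept_id"))
        if klass is not None:
            body["class"] = klass.to_fhir()
        period = {}
        if row.get("visit_start_date"):
            period["start"] = row["visit_start_date"]
        if row.get("visit_end_date"):
            period["end"] = row["visit_end_date"]
        if period:
            body["period"] = period
        body["subject"] = _patient_ref(row.get("person_id"))
        return FhirResource(
            "Encounter", body, local_ref("Encounter", "visit_occurrence", vid)
        )

    def build_condition(self, row: dict) -> FhirResource:
        cid = row["condition_occurrence_id"]
        body: dict = {"resourceType": "Condition"}
        no_end = row.get("condition_end_date") in (None, "")
        body["clinicalStatus"] = {
            "coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/condition-clinical",
                "code": "active" if no_end else "resolved",
            }]
        }
        body["category"] = [{
            "coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/condition-category",
                "code": "encounter-diagnosis",
                "display": "Encounter Diagnosis",
            }]
        }]
        # dual coding: SNOMED standard first, ICD source second
        codings = []
        standard = self._row_coding(row, "condition")
        if standard is not None:
            codings.append(standard)
        source = self._row_coding(row, "condition_source")
        if source is not None:
            codings.append(source)
        if codings:
            body["code"] = CodeableConcept(
                coding=codings, text=row.get("condition_source_value")
            ).to_fhir()
        elif row.get("condition_source_value"):
            body["code"] = {"text": row["condition_source_value"]}
        body["subject"] = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        if enc is not None:
            body["encounter"] = enc
        if row.get("condition_start_date"):
            body["onsetDateTime"] = row["condition_start_date"]
        if row.get("condition_end_date"):
            body["abatementDateTime"] = row["condition_end_date"]
        return FhirResource(
            "Condition", body, local_ref("Condition", "condition_occurrence", cid)
        )

    def build_coverage(self, row: dict) -> FhirResource:
        pid = row["payer_plan_period_id"]
        body: dict = {"resourceType": "Coverage", "status": "active"}
        payer = self._translate_coding("coverage-type", row.get("payer_concept_id"))
        if payer is not None:
            body["type"] = CodeableConcept(coding=[payer]).to_fhir()
        elif row.get("payer_source_value"):
            body["type"] = {"text": row["payer_source_value"]}
        body["beneficiary"] = _patient_ref(row.get("person_id"))
        period = {}
        if row.get("payer_plan_period_start_date"):
            period["start"] = row["payer_plan_period_start_date"]
        if row.get("payer_plan_period_end_date"):
            period["end"] = row["payer_plan_period_end_date"]
        if period:
            body["period"] = period
        return FhirResource(
            "Coverage", body, local_ref("Coverage", "payer_plan_period", pid)
        )

    # -- observations ---------------------------------------------------------

    @staticmethod
    def observation_profile(row: dict, table: str) -> str:
        """Dispatch to one of the three Observation profile variants."""
        if table == "measurement":
            return "laboratory"
        if row.get("is_smoking_aggregate"):
            return "smoking"
        return "non-smoking"

    def build_observation(self, row: dict, profile: str) -> Optional[FhirResource]:
        if profile == "laboratory":
            return self._build_lab_observation(row)
        if profile == "smoking":
            return self._build_smoking_observation(row)
        return self._build_social_observation(row)

    def _category(self, code: str) -> list[dict]:
        return [{
            "coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/observation-category",
                "code": code,
            }]
        }]

    def _build_lab_observation(self, row: dict) -> Optional[FhirResource]:
        code = self._row_coding(row, "measurement")
        if code is None and row.get("value_as_number") is None:
            log.warning("measurement %s has no code and no value; skipped",
                        row.get("measurement_id"))
            return None
        body: dict = {"resourceType": "Observation", "status": "final"}
        body["category"] = self._category("laboratory")
        if code is not None:
            body["code"] = CodeableConcept(
                coding=[code], text=row.get("measurement_source_value")
            ).to_fhir()
        elif row.get("measurement_source_value"):
            body["code"] = {"text": row["measurement_source_value"]}
        body["subject"] = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        if enc is not None:
            body["encounter"] = enc
        when = row.get("measurement_datetime") or row.get("measurement_date")
        if when:
            body["effectiveDateTime"] = when
        if row.get("value_as_number") is not None:
            quantity: dict = {"value": row["value_as_number"]}
            unit = self._row_coding(row, "unit")
            if unit is not None:
                quantity["unit"] = unit.display or unit.code
                quantity["system"] = unit.system
                quantity["code"] = unit.code
            elif row.get("unit_source_value"):
                quantity["unit"] = row["unit_source_value"]
            body["valueQuantity"] = quantity
        return FhirResource(
            "Observation", body,
            local_ref("Observation", "measurement", row["measurement_id"]),
        )

    def _build_smoking_observation(self, row: dict) -> FhirResource:
        responses = [
            SmokingResponse(question=r["question"], answer=r.get("answer"))
            for r in row.get("smoking_responses", [])
        ]
        status_coding = self.smoking_rules.map_code(responses, self.terminology)
        body: dict = {"resourceType": "Observation", "status": "final"}
        body["category"] = self._category("social-history")
        body["code"] = CodeableConcept(coding=[SMOKING_STATUS_CODING]).to_fhir()
        body["subject"] = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        if enc is not None:
            body["encounter"] = enc
        when = row.get("observation_datetime") or row.get("observation_date")
        if when:
            body["effectiveDateTime"] = when
        # full concatenated survey string always retained as text
        body["valueCodeableConcept"] = CodeableConcept(
            coding=[status_coding], text=row.get("observation_source_value")
        ).to_fhir()
        return FhirResource(
            "Observation", body,
            local_ref("Observation", "observation", row["observation_id"]),
        )

    def _build_social_observation(self, row: dict) -> Optional[FhirResource]:
        code = self._row_coding(row, "observation")
        has_value = (
            row.get("value_as_number") is not None
            or row.get("value_as_string") not in (None, "")
        )
        if code is None and not has_value:
            log.warning("observation %s has no code and no value; skipped",
                        row.get("observation_id"))
            return None
        body: dict = {"resourceType": "Observation", "status": "final"}
        body["category"] = self._category("social-history")
        if code is not None:
            body["code"] = CodeableConcept(
                coding=[code], text=row.get("observation_source_value")
            ).to_fhir()
        elif row.get("observation_source_value"):
            body["code"] = {"text": row["observation_source_value"]}
        body["subject"] = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        if enc is not None:
            body["encounter"] = enc
        when = row.get("observation_datetime") or row.get("observation_date")
        if when:
            body["effectiveDateTime"] = when
        if row.get("value_as_number") is not None:
            body["valueQuantity"] = {"value": row["value_as_number"]}
        elif row.get("value_as_string") not in (None, ""):
            body["valueString"] = row["value_as_string"]
        return FhirResource(
            "Observation", body,
            local_ref("Observation", "observation", row["observation_id"]),
        )

    # -- medications ----------------------------------------------------------

    def route_drug_exposure(self, row: dict) -> Optional[str]:
        """immunization | request | administration | dispense | None (skip)."""
        if row.get("drug_vocabulary") == "CVX":
            return "immunization"
        dtype = row.get("drug_type_concept_id")
        route = self.routing.get(int(dtype)) if dtype not in (None, "") else None
        if route is None:
            log.warning("drug_exposure %s: unknown drug_type_concept_id %s; skipped",
                        row.get("drug_exposure_id"), dtype)
            return None
        if route == "skip":
            log.info("drug_exposure %s: patient-reported row skipped",
                     row.get("drug_exposure_id"))
            return None
        return route

    def infer_medication_status(self, row: dict, family: str) -> str:
        if family == "request":
            return "stopped" if row.get("stop_reason") not in (None, "") else "unknown"
        # administration / dispense
        end = row.get("drug_exposure_end_date") or row.get("drug_exposure_end_datetime")
        return "completed" if end not in (None, "") else "in-progress"

    def resolve_requester(self, row: dict) -> Optional[dict]:
        """First available provider per the configured precedence, else None."""
        for field_name in self.requester_precedence:
            value = row.get(field_name)
            if value not in (None, ""):
                return {"reference": f"Practitioner/{int(value)}",
                        "display": f"Practitioner {int(value)}"}
        log.warning("drug_exposure %s: no requester available; field left blank",
                    row.get("drug_exposure_id"))
        return None

    def _medication_code(self, row: dict) -> dict:
        codings = []
        rx = self._row_coding(row, "drug")
        if rx is not None:
            codings.append(rx)
        ndc = self._row_coding(row, "drug_source")
        if ndc is not None:
            codings.append(ndc)
        if codings:
            return CodeableConcept(
                coding=codings, text=row.get("drug_name") or row.get("drug_source_value")
            ).to_fhir()
        return {"text": row.get("drug_source_value") or "unknown medication"}

    def build_medication(self, row: dict) -> FhirResource:
        ref = local_ref("Medication", "drug_concept", row["drug_concept_id"])
        body = {"resourceType": "Medication", "code": self._medication_code(row)}
        return FhirResource("Medication", body, ref)

    def _dose_quantity(self, row: dict) -> Optional[dict]:
        # included only when the source quantity field is available;
        # multi-ingredient dose computation is deliberately not attempted
        if row.get("quantity") is None:
            return None
        dose: dict = {"value": row["quantity"]}
        unit = self._row_coding(row, "amount_unit")
        if unit is not None:
            dose["unit"] = unit.display or unit.code
            dose["system"] = unit.system
            dose["code"] = unit.code
        return dose

    def build_medication_family(
        self, row: dict, family: str
    ) -> tuple[FhirResource, Optional[FhirResource]]:
        """(event resource, Medication or None if already emitted this run)."""
        med_ref = local_ref("Medication", "drug_concept", row["drug_concept_id"])
        medication = None
        drug_cid = int(row["drug_concept_id"])
        if drug_cid not in self._medications_emitted:
            medication = self.build_medication(row)
            self._medications_emitted.add(drug_cid)

        deid = row["drug_exposure_id"]
        subject = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        status = self.infer_medication_status(row, family)
        start = row.get("drug_exposure_start_datetime") or row.get("drug_exposure_start_date")
        end = row.get("drug_exposure_end_datetime") or row.get("drug_exposure_end_date")
        dose = self._dose_quantity(row)

        if family == "request":
            body: dict = {
                "resourceType": "MedicationRequest",
                "status": status,
                "intent": "order",
                "medicationReference": _ref(med_ref),
                "subject": subject,
            }
            if enc is not None:
                body["encounter"] = enc
            if start:
                body["authoredOn"] = start
            requester = self.resolve_requester(row)
            if requester is not None:
                body["requester"] = requester
            dosage: dict = {}
            if row.get("sig"):
                dosage["text"] = row["sig"]
            if dose is not None:
                dosage["doseAndRate"] = [{"doseQuantity": dose}]
            if dosage:
                body["dosageInstruction"] = [dosage]
            rtype = "MedicationRequest"
        elif family == "administration":
            body = {
                "resourceType": "MedicationAdministration",
                "status": status,
                "medicationReference": _ref(med_ref),
                "subject": subject,
            }
            if enc is not None:
                body["context"] = enc
            if start and end:
                body["effectivePeriod"] = {"start": start, "end": end}
            elif start:
                body["effectiveDateTime"] = start
            if dose is not None:
                body["dosage"] = {"dose": dose}
            rtype = "MedicationAdministration"
        elif family == "dispense":
            body = {
                "resourceType": "MedicationDispense",
                "status": status,
                "medicationReference": _ref(med_ref),
                "subject": subject,
            }
            if start:
                body["whenHandedOver"] = start
            if dose is not None:
                body["quantity"] = dose
            rtype = "MedicationDispense"
        else:
            raise ValueError(f"unknown medication family {family!r}")

        event = FhirResource(rtype, body, local_ref(rtype, "drug_exposure", deid))
        return event, medication

    def build_immunization(self, row: dict) -> FhirResource:
        if row.get("drug_vocabulary") != "CVX":
            raise ValueError(
                f"drug_exposure {row.get('drug_exposure_id')}: not a CVX row, "
                "not routed to Immunization"
            )
        body: dict = {"resourceType": "Immunization", "status": "completed"}
        cvx = self._row_coding(row, "drug")
        body["vaccineCode"] = CodeableConcept(
            coding=[cvx] if cvx else [], text=row.get("drug_source_value")
        ).to_fhir() if cvx else {"text": row.get("drug_source_value") or "unknown vaccine"}
        body["patient"] = _patient_ref(row.get("person_id"))
        enc = _encounter_ref(row.get("visit_occurrence_id"))
        if enc is not None:
            body["encounter"] = enc
        when = row.get("drug_exposure_start_datetime") or row.get("drug_exposure_start_date")
        if when:
            body["occurrenceDateTime"] = when
        return FhirResource(
            "Immunization", body,
            local_ref("Immunization", "drug_exposure", row["drug_exposure_id"]),
        )

    # ---------------------------------------------------------------- bundles

    def transform_rows(self, table: str, rows: list[dict]) -> list[FhirResource]:
        resources: list[FhirResource] = []
        for row in rows:
            if table == "person":
                r = self.build_patient(row)
                if r is not None:
                    resources.append(r)
            elif table == "visit_occurrence":
                resources.append(self.build_encounter(row))
            elif table == "condition_occurrence":
                resources.append(self.build_condition(row))
            elif table == "payer_plan_period":
                resources.append(self.build_coverage(row))
            elif table in ("observation", "measurement"):
                profile = self.observation_profile(row, table)
                r = self.build_observation(row, profile)
                if r is not None:
                    resources.append(r)
            elif table == "drug_exposure":
                route = self.route_drug_exposure(row)
                if route is None:
                    continue
                if route == "immunization":
                    resources.append(self.build_immunization(row))
                else:
                    event, medication = self.build_medication_family(row, route)
                    resources.append(event)
                    if medication is not None:
                        resources.append(medication)
            else:
                raise KeyError(f"no builder for OMOP table {table!r}")
        return resources

    def transform_document(self, doc: OmopJsonDocument) -> Bundle:
        resources = self.transform_rows(doc.table, doc.rows)
        return self.wrap_bundle(resources, source=f"{doc.table}_{doc.index}")

    def wrap_bundle(
        self, resources: Sequence[FhirResource], source: str = "batch"
    ) -> Bundle:
        entries = []
        seen: set[str] = set()
        for r in resources:
            if r.local_ref in seen:
                raise ValueError(f"duplicate fullUrl in bundle: {r.local_ref}")
            seen.add(r.local_ref)
            entries.append({"fullUrl": r.local_ref, "resource": r.body})
        bundle_id = str(uuid.uuid5(_NAMESPACE, f"Bundle|{source}"))
        # carries OMOP provenance metadata; flagged downstream as an
        # unknown (but harmless) extension
        extension = [{"url": "urn:omopfhir:omop-cdm-source", "valueString": source}]
        return Bundle(type="collection", entries=entries, id=bundle_id, extension=extension)
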
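# Subset conformance rules: required elements and code bindings per resource
# type.  Severity per finding category is fixed in code (validate.SEVERITY).
# Period-ordering invariants and coding/terminology checks are generic and
# applied to every resource; they are not listed per type.
resources:
  Patient:
    required: [gender, birthDate]
    code_bindings:
      - path: gender
        allowed: [male, female, other, unknown]
  Encounter:
    required: [status, class, subject]
  Condition:
    required: [code, subject, category, clinicalStatus]
  Coverage:
    required: [status, beneficiary]
  Observation:
    required: [status, code, subject, category]
  MedicationRequest:
    required: [status, intent, medicationReference, subject, requester]
  MedicationAdministration:
    required: [status, medicationReference, subject, "effective[x]"]
  MedicationDispense:
    required: [status, medicationReference, subject]
  Medication:
    required: [code]
    require_coding_from:
      - path: code
        system: http://www.nlm.nih.gov/research/umls/rxnorm
  Immunization:
    required: [status, vaccineCode, patient, occurrenceDateTime]

# Extension URLs the rule set recognises; any other URL is reported as an
# informational unknown-extension finding.
known_extensions:
  - http://hl7.org/fhir/us/core/StructureDefinition/us-core-race
  - http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity
  - http://hl7.org/fhir/us/core/StructureDefinition/us-core-birthsex
  - urn:ietf:rfc:3986

# Code systems accepted structurally without a CONCEPT-table lookup
# (HL7-maintained vocabularies the OMOP CONCEPT extract does not carry).
structural_systems:
  - http://hl7.org/fhir/administrative-gender
  - http://terminology.hl7.org/CodeSystem/v3-AdministrativeGender
  - http://terminology.hl7.org/CodeSystem/v3-ActCode
  - http://terminology.hl7.org/CodeSystem/condition-clinical
  - http://terminology.hl7.org/CodeSystem/condition-category
  - http://terminology.hl7.org/CodeSystem/observation-category
  - http://terminology.hl7.org/CodeSystem/medicationrequest-status
  - urn:oid:2.16.840.1.113883.6.238
  - urn:omopfhir:payer-type
  - http://unitsofmeasure.org
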
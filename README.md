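# omopfhir

A standards-based ETL pipeline for chronic disease surveillance: clinical
data held in the **OMOP Common Data Model v5.3** is transformed into
**US Core-style FHIR R4 resources**, exchanged through an emulated
**Bulk FHIR** `$import`/`$export` flow, and flattened into a
surveillance-style relational database. The package is aimed at health
informatics teams who hold OMOP research data warehouses and want a
FHIR-shaped, population-level extraction path instead of bespoke
per-institution CSV ETL.

## The pipeline

Six stages, each independently runnable:

1. **Extract** — cohort-filter the OMOP tables (≥1 clinical
   inpatient/outpatient/ED visit on or after 2017-01-01; age ≥2 years;
   5-digit zip and state of residence) and emit single-key *OMOP JSON*
   documents `{"<table>": [row, …]}`, partitioned into `CHUNKSIZE`-row
   chunks. Each row carries everything one FHIR resource needs: PERSON is
   LEFT JOINed with DEATH and LOCATION, DRUG_EXPOSURE with DRUG_STRENGTH,
   every `*_concept_id` is resolved against CONCEPT, and multi-row smoking
   surveys are pre-concatenated per encounter.
2. **Transform** — native builder functions map 11 OMOP tables onto 10 FHIR
   resource types (Patient, Encounter, Condition, Coverage, Observation in
   three profile variants — laboratory / smoking / non-smoking,
   MedicationRequest, MedicationAdministration, MedicationDispense,
   Medication, Immunization), wrapping each document's resources in a
   collection Bundle with deterministic UUIDv5 `urn:uuid` references.
   Terminology goes through local FHIR ConceptMaps only. Resources carry
   *dual coding*: the US Core-required standard code (SNOMED, RxNorm) first
   and the nonstandard EHR source code (ICD-9/10-CM, NDC) second.
3. **Validate** (optional) — a data-driven subset conformance checker with a
   fixed eight-category taxonomy (element-cardinality, code-not-in-system
   and invariant violations as errors; value-set and label findings as
   warnings; unknown extensions/code systems as info). The non-compliance
   rate counts resources with ≥1 error over resources checked.
   Non-conformant resources are reported, never dropped.
4. **Import** — an in-process FHIR server emulation: full refresh,
   server-generated integer ids, two-pass `urn:uuid` reference rewriting,
   no referential integrity check (dangling references are logged).
5. **Export** — Bulk-FHIR-style NDJSON, one file per resource type, with a
   status-response-shaped manifest.
6. **Load** — NDJSON flattened into a minimal surveillance schema (patient,
   encounter, diagnosis, lab_result, prescription, immunization,
   social_history), including the conversion of interval-based Coverage
   resources into one primary payer per encounter via a configurable payer
   hierarchy (highest-ranked payer whose period contains the encounter
   start date; ties to the earliest period start).

Domain rules worth knowing: MedicationRequest.status is inferred as
`stopped`/`unknown` from the OMOP stop_reason, administration/dispense
status as `completed`/`in-progress` from the end date; the requester falls
back from the visit-level provider to the drug row's provider and is left
blank (knowingly non-conformant) when both are absent; doseQuantity is
emitted only when the source quantity exists; Immunizations are built only
from CVX-coded drug rows; and the smoking survey's concatenated string,
e.g.

```
(Chew:No) – (CigarettePacksPerDay:<20) – (Cigarettes:No) – … – (TobaccoUse:Yes) – (TobaccoUseInYears:+)
```

is collapsed by an ordered, editable rule table onto one of the **six**
SNOMED codes the US Core smoking-status profile allows, while the full
string is retained as `valueCodeableConcept.text`.

A seeded synthetic OMOP generator (`omopfhir.synthgen`) produces all 11
tables with targeted edge-case injection (missing requester, inverted
coverage periods, 4-digit zips, under-age persons, pre-2017-only visits,
…), so the whole pipeline is exercisable without any real data.

## Worked example

```bash
omopfhir synth --n 200 --seed 1 --out /tmp/omop
omopfhir run --omop /tmp/omop --out /tmp/run --as-of 2023-01-01 --chunk-size 500
```

or from Python (`python examples/04_end_to_end_surveillance.py`), which
prints:

```
   extract: ok  {'cohort_size': 176, 'table_rows': {'person': 176, 'visit_occurrence': 513, ...}, 'documents': 9}
 transform: ok  {'bundles': 9, 'resources': {'Patient': 176, 'Encounter': 513, 'Condition': 415,
                 'Coverage': 218, 'Observation': 738, 'MedicationRequest': 89, 'Medication': 4,
                 'MedicationAdministration': 61, 'MedicationDispense': 55, 'Immunization': 36}}
  validate: ok  {'resources_checked': 2305, 'resources_with_error': 2, 'non_compliance_rate': 0.00087}
    import: ok  {'imported': {...}, 'unresolved_references': 0}
    export: ok  {'exported': {...}}
      load: ok  {'loaded': {'patient': 176, 'encounter': 513, 'diagnosis': 415, ...}, 'payers_assigned': 277}

encounters by primary payer: {None: 236, 'COMMERCIAL': 67, 'MEDICAID': 67, 'MEDICARE': 88, 'SELFPAY': 55}
```

Reading it: 176 of 200 synthetic persons pass the three cohort criteria;
row counts are conserved 1:1 across every stage boundary for the 1:1
domains (person→Patient→patient, visit→Encounter→encounter, …); two
resources carry injected defects, giving a non-compliance rate well under
1%; and 277 encounters fall inside at least one coverage interval and
receive a primary payer.

The other scripts in `examples/` demonstrate extraction and chunking,
dual coding and the smoking collapse, and the validator taxonomy.

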
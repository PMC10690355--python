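# Methods

## Scope and model

The package implements a batch OMOP-to-FHIR-to-surveillance ETL. The unit
of transformation is the *OMOP JSON* document: a single-key JSON object
`{"<table>": [row, …]}` whose rows are fully self-contained — all joins and
concept resolution happen at extraction time, so the resource builders are
pure functions of one row. This mirrors the batch-transformation model in
which a template engine consumes one row per resource and wraps each
document's output in a FHIR Bundle; here the templates are native Python
builders rather than an external JSON-to-JSON transformation language.

### Cohort

Three inclusion criteria, all required: at least one visit of an allowed
"clinical" class starting on or after `min_visit_date` (default
2017-01-01); age at `as_of_date` of at least `min_age_years` (default 2);
and a linked LOCATION row with a 5-digit zip and a non-empty state. The
allowed classes default to the OMOP standard visit concepts 9201
(inpatient), 9202 (outpatient), 9203 (emergency department); the ids are
configurable because the class names, not the ids, define the criterion.
Age needs an anchor date the source tables do not provide; the package
anchors it at `as_of_date` (default: the extraction run date), matching
full-refresh semantics where each run re-evaluates the cohort. Zip
validity is exactly five ASCII digits after trimming; a ZIP+4 value is
truncated to its 5-digit prefix, since the surveillance target mandates
5-digit zips.

### Chunking

`ExtractionConfig.chunk_size` (CHUNKSIZE) bounds the number of rows per
document. Every document holds exactly `chunk_size` rows except the final
partial chunk (arbitrary table sizes make an exact-only rule impossible).
Chunking is a pure partition of the shaped, primary-key-sorted table, which
gives two tested invariants: concatenating all chunks reproduces the shaped
table, and the multiset of FHIR resources produced from a table is
identical for any chunk size (tested at 1, 7, and 1000).

### Terminology

All translation is local. Demographic and administrative codes go through
FHIR R4 ConceptMap JSON files whose source codes are stringified OMOP
concept_ids; clinical codes are resolved directly against the loaded
CONCEPT table, with a registry mapping OMOP vocabulary_ids to canonical
code-system URIs (SNOMED, RxNorm, LOINC, CVX, NDC, ICD-9/10-CM, UCUM;
overridable via `apply_registry_overrides`). An unmatched translation is
an explicit result, never a silent empty list; builders respond by
omitting the element or falling back to a text-only CodeableConcept with a
logged warning — fields are left blank rather than filled with fabricated
values, even where that produces a knowingly non-conformant resource.
ConceptMap `equivalence` attributes are parsed but not used for filtering.

### Dual coding

Condition.code lists the standard SNOMED coding first and the ICD source
coding second; Medication.code lists RxNorm first and NDC second. The
source coding is included only when the source concept resolves.

### Medications

One OMOP DRUG_EXPOSURE table fans out to five resource types. Routing:
rows whose drug concept belongs to the CVX vocabulary become
Immunizations; otherwise drug_type_concept_id selects
request/administration/dispense through a configurable table
(prescription written → MedicationRequest; inpatient administration →
MedicationAdministration; pharmacy dispense → MedicationDispense;
patient-reported → skipped, as MedicationStatement is out of scope).
Status inference: a request is `stopped` when stop_reason is present and
`unknown` otherwise; administrations and dispenses are `completed` when an
end date exists and `in-progress` otherwise. The requester is the first
available of the visit-level provider and the drug row's provider (the
precedence is configurable since the source data leaves it ambiguous);
with neither, the element is omitted and the resource flows on.
doseQuantity is emitted only when the source `quantity` field is present;
computing doses for multi-ingredient medications is explicitly not
attempted. Medication resources are deduplicated per distinct
drug_concept_id per run. RxNorm-coded vaccine rows are *not* remapped to
CVX; they route as ordinary medication events.

### Smoking

Survey answers arrive as up to 10 OBSERVATION rows per encounter. The
extraction stage concatenates them into one string of
`(question:answer)` components sorted by question name and joined with
`" – "` (en dash); an answerless free-text entry renders without a colon.
Parsing is the exact inverse on generator output (property-tested with
500 random response lists). The concatenation is collapsed onto one of
six SNOMED codes — the US Core smoking-status subset (449868002,
428041000124106, 8517006, 266919005, 77176002, 266927001) — by an ordered
first-match rule table keyed on TobaccoUse, then Cigarettes, then
TobaccoUseInYears, shipped as editable YAML with a default of
unknown-if-ever-smoked; the set size (6) is asserted at pipeline start.
The rule table itself is a design choice: the source data collapses
thousands of answer combinations onto six codes without publishing the
mapping, so the package ships an auditable table rather than hard-coded
logic. The full concatenated string is always retained as
`valueCodeableConcept.text`.

### Observation profiles

Three variants: MEASUREMENT rows become laboratory Observations
(LOINC code, valueQuantity with UCUM unit); aggregated smoking rows become
smoking Observations (fixed LOINC 72166-2 code, SNOMED value); all other
OBSERVATION rows become non-smoking social-history Observations.

### Validation

A deliberate subset validator, not a StructureDefinition engine:
required-element and binding rules are data (YAML per resource type),
while three generic checks run everywhere — period ordering
(`start <= end`), coding verification against the loaded CONCEPT table
(standing in for a terminology server), and extension-URL recognition.
The eight finding categories pair fixedly with severities
(cardinality/code-not-in-system/invariant → error; value-set and label
findings → warning; unknown extension/code system → info). Label
comparison normalizes whitespace and truncates at 256 characters, the
source system's label limit. US-edition-specific SNOMED failures depend
on which terminology edition a server loads and are documented as a
category only, not computed. The non-compliance rate is resources with at
least one error over resources checked; warnings and info findings never
mark a resource non-compliant, and validation neither mutates nor drops
anything.

### Server emulation and bulk exchange

`$import` is a full refresh with monotonically increasing per-type integer
ids, deterministic given input order. References are rewritten in a second
pass from the `urn:uuid` fullUrl map; unresolved references are logged and
kept — the emulated server performs no referential integrity check.
Bundles are `collection` type (transaction semantics are unnecessary when
the server rewrites ids itself), and each carries a provenance extension
that validation intentionally flags as unknown. `$export` is modelled as a
synchronous call writing one NDJSON file per type and returning a
status-response-shaped manifest; job polling, HTTP, auth, and group
filtering are out of scope.

### Surveillance load

The target schema is a documented minimal subset of an ESP-style
surveillance database — the real DDL is not public, so the tables cover
the mapped data domains (patient, encounter, diagnosis, lab_result,
prescription, immunization, social_history) honestly rather than
pretending to replicate it. The coverage conversion anchors on the
encounter *start* date: among coverage intervals containing that date
(closed intervals; null end = open-ended), the payer type ranked highest
in the configurable hierarchy wins; rank ties go to the earliest period
start, then payer-code order, making selection invariant to input order.
Default hierarchy: MEDICARE > MEDICAID > COMMERCIAL > SELFPAY, under a
local payer-type code system since no standard typology is mandated by
the target. Disease-detection case logic is out of scope.

## Synthetic data generator

The generator emulates the *structural* features the pipeline exercises:
referential consistency across all 11 tables; a CONCEPT table covering
every referenced concept plus all ConceptMap source codes; multi-row
smoking surveys (≤10 rows, the documented survey maximum); drug rows
spanning all five routes (guaranteed per run by deterministic round-robin
typing, with one row per route pinned to the first cohort-eligible
person); and edge cases injected at configurable per-row/per-person
probabilities. Defaults, chosen once as small realistic rates: missing
requester 0.02, stop_reason present 0.30, overlapping coverage 0.25,
inverted period 0.005, missing zip 0.05, under-age 0.03, pre-2017-only
visits 0.05, multi-row smoking 0.50, non-CVX vaccine 0.10.
`SynthConfig.clean()` zeroes the defect rates for clean-data runs. Visit
counts per person are 1 + Poisson(2), conditions Poisson(0.8) and labs
Poisson(1.0) per visit, drugs Poisson(1.5) per person; lab values are
Gaussian around clinically plausible means. Ages are uniform 3–89 years
against a fixed reference date (2023-01-01 by default) so runs are
reproducible regardless of wall-clock date.

What the generator does **not** emulate — and therefore what passing
tests do not show — includes longitudinal disease trajectories, realistic
code frequency distributions, free-text idiosyncrasies of real EHR source
values, and vocabulary-version drift. Tests demonstrate the
transformation and exchange machinery is correct on structurally faithful
data, not that real-data error rates would match.

## Numerical and procedural choices

- Determinism: all randomness flows from a single numpy `default_rng`
  seed; resource identity is UUIDv5 over (resource type, source table,
  primary key), so re-running any stage is byte-identical.
- Dates serialize as ISO-8601 (`YYYY-MM-DD`, datetimes
  `YYYY-MM-DDThh:mm:ss` with a configurable fixed UTC offset applied at
  extraction), satisfying FHIR's dateTime grammar.
- Degenerate inputs: empty tables yield empty document lists; an empty
  response list renders as the empty string; zero resources summarize to
  rate 0 with an explicit empty flag; inverted periods are emitted as-is
  and only flagged.
- Problem sizes: the test suite and acceptance script run the full
  pipeline at 1000 synthetic patients (≈13 000 resources) and the
  defect-recovery check at 800 patients — large enough for binomial ±3σ
  bands on injected rates while keeping a full run in seconds.

## Known limitations

- The validator covers required elements, the bindings listed in its rule
  file, period invariants, and terminology existence — not FHIRPath
  invariants, slicing, or profile snapshots.
- Practitioner references are emitted as literal `Practitioner/<id>`
  references without Practitioner resources (the surveillance target only
  needs the identifier).
- The MENDS/ESP schema here is a minimal documented subset, and the
  shipped ConceptMaps cover the demographic/administrative maps the
  builders need; production deployments would extend both.
- Whistle-language execution, remote terminology services, HTTP transport
  and real FHIR servers, and full-scale production counts/timings are out
  of scope by design.
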
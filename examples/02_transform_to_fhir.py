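"""Transform OMOP rows into US Core-style FHIR resources.

Shows the two signature behaviours: dual coding (standard SNOMED/RxNorm
coding first, nonstandard ICD/NDC source coding second) and the smoking
survey collapse (many survey rows -> one Observation carrying one of six
SNOMED codes plus the full concatenated string as text).
"""

import json

from omopfhir import ResourceTransformer, parse_smoking_source_value
from omopfhir.pipeline import build_terminology
from omopfhir.synthgen import WORKED_SMOKING_STRING, worked_example_fixture

terminology = build_terminology(None)
transformer = ResourceTransformer(terminology)

# --- dual-coded Condition -------------------------------------------------
row = dict(worked_example_fixture()["condition"].rows[0],
           condition_code="59621000", condition_name="Essential hypertension",
           condition_vocabulary="SNOMED", condition_source_code="I10",
           condition_source_name="Essential (primary) hypertension",
           condition_source_vocabulary="ICD10CM")
condition = transformer.build_condition(row)
print("Condition.code.coding:")
print(json.dumps(condition.body["code"]["coding"], indent=1))

# --- smoking Observation ----------------------------------------------------
responses = parse_smoking_source_value(WORKED_SMOKING_STRING)
print(f"\nsmoking survey: {len(responses)} components, first =",
      (responses[0].question, responses[0].answer))
obs = transformer.build_observation({
    "observation_id": 1, "person_id": 1, "visit_occurrence_id": 1,
    "observation_date": "2019-04-01", "is_smoking_aggregate": True,
    "observation_source_value": WORKED_SMOKING_STRING,
    "smoking_responses": [
        {"question": r.question, "answer": r.answer} for r in responses],
}, "smoking")
vcc = obs.body["valueCodeableConcept"]
print("collapsed SNOMED code:", vcc["coding"][0]["code"],
      "-", vcc["coding"][0]["display"])
print("full survey string retained as text:", vcc["text"] == WORKED_SMOKING_STRING)
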
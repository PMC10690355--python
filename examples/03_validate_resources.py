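"""Subset conformance validation with the fixed error taxonomy.

A MedicationRequest whose requester could not be inferred is knowingly
non-conformant (an element-cardinality error) but is never dropped; an
inverted coverage period is an invariant violation kept as-is.
"""

import tempfile
from pathlib import Path

from omopfhir import SynthConfig, Validator, generate, load_omop
from omopfhir.pipeline import build_terminology

workdir = Path(tempfile.mkdtemp())
generate(SynthConfig.clean(n_persons=20, seed=5), workdir / "omop")
store = load_omop(workdir / "omop")
terminology = build_terminology(None)
validator = Validator.from_store(terminology, store)

bad_request = {
    "resourceType": "MedicationRequest", "status": "unknown", "intent": "order",
    "medicationReference": {"reference": "Medication/1"},
    "subject": {"reference": "Patient/1"},
    # requester deliberately absent: left blank rather than fabricated
}
bad_coverage = {
    "resourceType": "Coverage", "status": "active",
    "beneficiary": {"reference": "Patient/1"},
    "period": {"start": "2020-01-01", "end": "2019-01-01"},
}
good_patient = {"resourceType": "Patient", "gender": "female",
                "birthDate": "1980-02-03"}

summary = Validator.summarize(
    validator.validate_resource(r) for r in (bad_request, bad_coverage, good_patient))
print(summary.format_table())
# the rate counts resources with >=1 error-level finding, not findings
print(f"\n2 of 3 resources non-compliant -> rate {summary.non_compliance_rate:.3f}")
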
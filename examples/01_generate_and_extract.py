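"""Generate synthetic OMOP tables, apply the cohort filter, and chunk the
extract into single-key OMOP JSON documents.

The cohort keeps persons with >=1 clinical (inpatient/outpatient/ED) visit
on or after 2017-01-01, age >=2 years, and a 5-digit zip plus state.
"""

import tempfile
from datetime import date
from pathlib import Path

from omopfhir import CohortCriteria, ExtractionConfig, SynthConfig, generate, load_omop

workdir = Path(tempfile.mkdtemp())
generate(SynthConfig(n_persons=100, seed=7), workdir / "omop")

store = load_omop(workdir / "omop")
print("rows per table:", store.row_counts())

cohort = store.apply_cohort_filter(CohortCriteria(as_of_date=date(2023, 1, 1)))
print(f"cohort: {len(cohort)} of 100 persons pass all three criteria")

docs = store.extract_table_json(
    "condition_occurrence", ExtractionConfig(chunk_size=25), cohort)
print(f"condition extract: {len(docs)} documents of sizes",
      [len(d.rows) for d in docs])
# each document has exactly one top-level key: the OMOP table name
print("document keys:", [list(d.to_dict()) for d in docs[:1]])
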
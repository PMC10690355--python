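"""Shared fixtures: a clean synthetic OMOP corpus, its store/cohort, and a
terminology service with the shipped ConceptMaps — session-scoped since
generation and loading dominate test runtime."""

from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest

from omopfhir.omop_store import CohortCriteria, ExtractionConfig, load_omop
from omopfhir.pipeline import build_terminology
from omopfhir.synthgen import SynthConfig, generate
from omopfhir.transform import ResourceTransformer
from omopfhir.validate import Validator

AS_OF = date(2023, 1, 1)


@pytest.fixture(scope="session")
def clean_omop_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("omop_clean")
    generate(SynthConfig.clean(n_persons=60, seed=11), out)
    return out


@pytest.fixture(scope="session")
def dirty_omop_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("omop_dirty")
    generate(SynthConfig(n_persons=120, seed=11), out)
    return out


@pytest.fixture(scope="session")
def store(clean_omop_dir):
    return load_omop(clean_omop_dir)


@pytest.fixture(scope="session")
def cohort(store):
    return store.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF))


@pytest.fixture(scope="session")
def terminology():
    return build_terminology(None)


@pytest.fixture()
def transformer(terminology):
    # function-scoped: Medication dedup state must not leak between tests
    return ResourceTransformer(terminology)


@pytest.fixture(scope="session")
def validator(terminology, store):
    return Validator.from_store(terminology, store)


@pytest.fixture()
def extraction():
    return ExtractionConfig(chunk_size=10_000)
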
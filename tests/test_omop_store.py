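"""Store loading, cohort criteria, shaping joins, and chunk partitioning."""

from __future__ import annotations

import csv
import math
from datetime import date
from pathlib import Path

import pytest

from omopfhir.omop_store import (
    EXPECTED_COLUMNS,
    OMOP_TABLES,
    CohortCriteria,
    ExtractionConfig,
    load_omop,
    read_document,
    write_documents,
)

AS_OF = date(2023, 1, 1)


def write_omop_dir(path: Path, rows: dict[str, list[dict]]) -> Path:
    """Write all 11 CSVs, filling unspecified tables with headers only."""
    path.mkdir(parents=True, exist_ok=True)
    for table in OMOP_TABLES:
        cols = EXPECTED_COLUMNS[table]
        with open(path / f"{table}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(cols))
            writer.writeheader()
            for row in rows.get(table, []):
                writer.writerow({c: row.get(c, "") for c in cols})
    return path


def person_row(pid: int, **kw) -> dict:
    base = dict(person_id=pid, gender_concept_id=8532, year_of_birth=1990,
                month_of_birth=6, day_of_birth=15,
                birth_datetime="1990-06-15T00:00:00",
                race_concept_id=8527, ethnicity_concept_id=38003564,
                location_id=pid)
    base.update(kw)
    return base


def visit_row(vid: int, pid: int, start: str, concept: int = 9202, **kw) -> dict:
    base = dict(visit_occurrence_id=vid, person_id=pid,
                visit_concept_id=concept, visit_start_date=start,
                visit_end_date=start)
    base.update(kw)
    return base


def loc_row(lid: int, zip_code: str = "80045", state: str = "CO") -> dict:
    return dict(location_id=lid, zip=zip_code, state=state)


class TestLoad:
    def test_row_counts_match_csv_lines(self, clean_omop_dir, store):
        counts = store.row_counts()
        assert set(counts) == set(OMOP_TABLES)
        for table in OMOP_TABLES:
            with open(clean_omop_dir / f"{table}.csv", encoding="utf-8") as fh:
                n_lines = sum(1 for _ in csv.reader(fh)) - 1
            assert counts[table] == n_lines

    def test_empty_person_table_loads_with_zero_count(self, tmp_path):
        store = load_omop(write_omop_dir(tmp_path / "o", {}))
        assert store.row_counts()["person"] == 0

    def test_missing_table_is_fatal(self, tmp_path):
        d = write_omop_dir(tmp_path / "o", {})
        (d / "person.csv").unlink()
        with pytest.raises(FileNotFoundError, match="person"):
            load_omop(d)

    def test_duplicate_primary_key_names_the_key(self, tmp_path):
        d = write_omop_dir(tmp_path / "o", {
            "person": [person_row(1), person_row(1)],
        })
        with pytest.raises(ValueError, match="person_id"):
            load_omop(d)

    def test_unknown_column_is_ignored(self, tmp_path, caplog):
        d = write_omop_dir(tmp_path / "o", {})
        with open(d / "person.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["person_id", "gender_concept_id", "bogus_column"])
            w.writerow([1, 8507, "x"])
        store = load_omop(d)
        assert "bogus_column" not in store.table("person").columns
        assert store.row_counts()["person"] == 1


class TestCohortFilter:
    def _store(self, tmp_path, persons, visits, locations):
        return load_omop(write_omop_dir(tmp_path / "cohort", {
            "person": persons, "visit_occurrence": visits, "location": locations,
        }))

    def test_visit_before_2017_excluded(self, tmp_path):
        s = self._store(tmp_path, [person_row(1)],
                        [visit_row(1, 1, "2016-12-31")], [loc_row(1)])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == set()

    def test_under_two_years_excluded(self, tmp_path):
        baby = person_row(1, year_of_birth=2022, month_of_birth=1, day_of_birth=1,
                          birth_datetime="2022-01-01T00:00:00")
        s = self._store(tmp_path, [baby], [visit_row(1, 1, "2022-06-01")],
                        [loc_row(1)])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == set()

    def test_four_digit_zip_excluded(self, tmp_path):
        s = self._store(tmp_path, [person_row(1)], [visit_row(1, 1, "2018-03-01")],
                        [loc_row(1, zip_code="8000")])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == set()

    def test_all_criteria_met_included(self, tmp_path):
        s = self._store(tmp_path, [person_row(1)], [visit_row(1, 1, "2018-03-01")],
                        [loc_row(1, zip_code="80045", state="CO")])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == {1}

    def test_zip_plus_four_is_truncated_and_accepted(self, tmp_path):
        s = self._store(tmp_path, [person_row(1)], [visit_row(1, 1, "2018-03-01")],
                        [loc_row(1, zip_code="80045-1234")])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == {1}

    def test_non_clinical_visit_class_excluded(self, tmp_path):
        s = self._store(tmp_path, [person_row(1)],
                        [visit_row(1, 1, "2018-03-01", concept=9999)], [loc_row(1)])
        assert s.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF)) == set()

    def test_relaxing_a_criterion_yields_superset(self, store):
        base = store.apply_cohort_filter(CohortCriteria(as_of_date=AS_OF))
        earlier = store.apply_cohort_filter(
            CohortCriteria(min_visit_date=date(2015, 1, 1), as_of_date=AS_OF))
        younger = store.apply_cohort_filter(
            CohortCriteria(min_age_years=0, as_of_date=AS_OF))
        no_zip = store.apply_cohort_filter(
            CohortCriteria(require_zip5_and_state=False, as_of_date=AS_OF))
        assert base <= earlier and base <= younger and base <= no_zip


class TestShapingAndChunks:
    def test_single_key_document_shape(self, store, cohort):
        docs = store.extract_table_json(
            "condition_occurrence", ExtractionConfig(chunk_size=10_000), cohort)
        assert len(docs) == 1
        d = docs[0].to_dict()
        assert list(d) == ["condition_occurrence"]

    def test_chunk_sizes_follow_ceiling_arithmetic(self, store, cohort):
        rows = store.shaped_table("visit_occurrence", cohort)
        chunk = 10
        docs = store.extract_table_json(
            "visit_occurrence", ExtractionConfig(chunk_size=chunk), cohort)
        assert len(docs) == math.ceil(len(rows) / chunk)
        assert all(len(d.rows) == chunk for d in docs[:-1])
        assert len(docs[-1].rows) == len(rows) - chunk * (len(docs) - 1)

    def test_zero_cohort_rows_yield_empty_document_list(self, store):
        assert store.extract_table_json(
            "condition_occurrence", ExtractionConfig(chunk_size=5), set()) == []

    @pytest.mark.parametrize("chunk_size", [1, 7, 1000])
    def test_partition_completeness(self, store, cohort, chunk_size):
        """Concatenated chunks reproduce the shaped table, any chunk size."""
        for table in ("person", "condition_occurrence", "observation"):
            full = store.shaped_table(table, cohort)
            docs = store.extract_table_json(
                table, ExtractionConfig(chunk_size=chunk_size), cohort)
            concat = [r for d in docs for r in d.rows]
            assert concat == full

    def test_person_death_left_join_keeps_living_patients_null(self, store, cohort):
        rows = store.shaped_table("person", cohort)
        assert rows, "cohort person rows expected"
        assert all("death_date" in r for r in rows)
        assert any(r["death_date"] is None for r in rows)

    def test_concept_ids_resolve_in_shaped_rows(self, store, cohort):
        for row in store.shaped_table("condition_occurrence", cohort):
            assert row["condition_vocabulary"] == "SNOMED"
            assert row["condition_code"]

    def test_documents_round_trip_through_files(self, store, cohort, tmp_path):
        docs = store.extract_table_json(
            "person", ExtractionConfig(chunk_size=7), cohort)
        paths = write_documents(docs, tmp_path / "json")
        reread = [read_document(p) for p in sorted(paths)]
        assert [d.rows for d in reread] == [d.rows for d in docs]
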
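"""Surveillance-database loading and the coverage -> primary-payer rule."""

from __future__ import annotations

import json
import random
from datetime import date, timedelta

import pytest

from omopfhir.fhir_server import ExportManifest
from omopfhir.mends_import import (
    CoverageInterval,
    MendsDb,
    PayerHierarchy,
    coverage_to_encounter_payer,
    import_ndjson,
)


def _manifest(tmp_path, resources_by_type: dict[str, list[dict]]) -> ExportManifest:
    manifest = ExportManifest(request_time="2024-01-01T00:00:00+00:00")
    for rtype, bodies in resources_by_type.items():
        path = tmp_path / f"{rtype}.ndjson"
        with open(path, "w", encoding="utf-8") as fh:
            for body in bodies:
                fh.write(json.dumps(body) + "\n")
        manifest.output.append({"type": rtype, "url": str(path), "count": len(bodies)})
    return manifest


class TestPayerSelection:
    H = PayerHierarchy(("MEDICARE", "COMMERCIAL"))

    def test_highest_ranked_overlapping_payer_wins(self):
        coverages = [
            CoverageInterval("COMMERCIAL", date(2018, 1, 1), date(2018, 12, 31)),
            CoverageInterval("MEDICARE", date(2018, 1, 1), date(2018, 12, 31)),
        ]
        assert coverage_to_encounter_payer(date(2018, 6, 1), coverages, self.H) == "MEDICARE"

    def test_no_overlap_returns_none(self):
        coverages = [CoverageInterval("MEDICARE", date(2019, 1, 1), date(2019, 12, 31))]
        assert coverage_to_encounter_payer(date(2018, 6, 1), coverages, self.H) is None

    def test_single_overlap_returns_that_payer(self):
        coverages = [CoverageInterval("COMMERCIAL", date(2018, 1, 1), None)]
        assert coverage_to_encounter_payer(date(2020, 6, 1), coverages, self.H) == "COMMERCIAL"

    def test_closed_interval_includes_boundaries(self):
        c = CoverageInterval("MEDICARE", date(2018, 1, 1), date(2018, 12, 31))
        assert coverage_to_encounter_payer(date(2018, 1, 1), [c], self.H) == "MEDICARE"
        assert coverage_to_encounter_payer(date(2018, 12, 31), [c], self.H) == "MEDICARE"
        assert coverage_to_encounter_payer(date(2019, 1, 1), [c], self.H) is None

    def test_rank_tie_goes_to_earliest_period_start(self):
        coverages = [
            CoverageInterval("MEDICARE", date(2018, 3, 1), None),
            CoverageInterval("MEDICARE", date(2018, 1, 1), None),
        ]
        # both rank 0; earliest start wins regardless of list order
        assert coverage_to_encounter_payer(date(2018, 6, 1), coverages, self.H) == "MEDICARE"

    def test_selection_invariant_to_input_order(self):
        rng = random.Random(3)
        hierarchy = PayerHierarchy(("MEDICARE", "MEDICAID", "COMMERCIAL", "SELFPAY"))
        for _ in range(200):
            coverages = _random_coverages(rng)
            shuffled = list(coverages)
            rng.shuffle(shuffled)
            day = date(2018, 1, 1) + timedelta(days=rng.randint(0, 1000))
            assert (coverage_to_encounter_payer(day, coverages, hierarchy)
                    == coverage_to_encounter_payer(day, shuffled, hierarchy))

    def test_matches_exhaustive_scan_oracle_on_1000_random_cases(self):
        """Selection equals a brute-force scan over all (coverage, rank) pairs."""
        rng = random.Random(99)
        hierarchy = PayerHierarchy(("MEDICARE", "MEDICAID", "COMMERCIAL", "SELFPAY"))
        for _ in range(1000):
            coverages = _random_coverages(rng)
            day = date(2018, 1, 1) + timedelta(days=rng.randint(0, 1500))
            best_key, best_payer = None, None
            for c in coverages:
                inside = ((c.start is None or c.start <= day)
                          and (c.end is None or day <= c.end))
                if not inside:
                    continue
                key = (hierarchy.rank(c.payer_type), c.start or date.min,
                       c.payer_type or "")
                if best_key is None or key < best_key:
                    best_key, best_payer = key, c.payer_type
            assert coverage_to_encounter_payer(day, coverages, hierarchy) == best_payer

    def test_hierarchy_invariants(self):
        with pytest.raises(ValueError):
            PayerHierarchy(())
        with pytest.raises(ValueError):
            PayerHierarchy(("A", "A"))


def _random_coverages(rng: random.Random) -> list[CoverageInterval]:
    out = []
    for _ in range(rng.randint(0, 5)):
        start = date(2017, 1, 1) + timedelta(days=rng.randint(0, 1200))
        end = None if rng.random() < 0.2 else start + timedelta(days=rng.randint(0, 900))
        payer = rng.choice(["MEDICARE", "MEDICAID", "COMMERCIAL", "SELFPAY", "OTHER", None])
        out.append(CoverageInterval(payer, start, end))
    return out


class TestNdjsonLoad:
    def test_patient_lines_become_patient_rows(self, tmp_path):
        manifest = _manifest(tmp_path, {"Patient": [
            {"resourceType": "Patient", "id": str(i), "gender": "female",
             "birthDate": "1980-01-01"} for i in range(1, 4)]})
        db = MendsDb()
        report = import_ndjson(manifest, db)
        assert report.rows == {"patient": 3}
        assert db.count("patient") == 3

    def test_smoking_observation_routes_to_social_history(self, tmp_path):
        body = {
            "resourceType": "Observation", "id": "1", "status": "final",
            "category": [{"coding": [{"system": "x", "code": "social-history"}]}],
            "code": {"coding": [{"system": "http://loinc.org", "code": "72166-2"}]},
            "subject": {"reference": "Patient/1"},
            "valueCodeableConcept": {
                "coding": [{"system": "http://snomed.info/sct", "code": "77176002"}],
                "text": "(TobaccoUse:Yes)",
            },
        }
        db = MendsDb()
        import_ndjson(_manifest(tmp_path, {"Observation": [body]}), db)
        row = db.conn.execute(
            "SELECT code, value_code, text FROM social_history").fetchone()
        assert row == ("72166-2", "77176002", "(TobaccoUse:Yes)")

    def test_malformed_line_skipped_and_counted(self, tmp_path):
        path = tmp_path / "Patient.ndjson"
        path.write_text('{"resourceType": "Patient", "id": "1"}\nnot json\n')
        manifest = ExportManifest(request_time="t", output=[
            {"type": "Patient", "url": str(path), "count": 2}])
        db = MendsDb()
        report = import_ndjson(manifest, db)
        assert report.error_lines == 1
        assert db.count("patient") == 1

    def test_lab_observation_routes_to_lab_result(self, tmp_path):
        body = {
            "resourceType": "Observation", "id": "2", "status": "final",
            "category": [{"coding": [{"system": "x", "code": "laboratory"}]}],
            "code": {"coding": [{"system": "http://loinc.org", "code": "2093-3"}]},
            "subject": {"reference": "Patient/1"},
            "valueQuantity": {"value": 187.0, "unit": "milligram per deciliter"},
        }
        db = MendsDb()
        import_ndjson(_manifest(tmp_path, {"Observation": [body]}), db)
        assert db.conn.execute("SELECT value FROM lab_result").fetchone()[0] == 187.0

    def test_encounter_payer_assignment_end_to_end(self, tmp_path):
        resources = {
            "Patient": [{"resourceType": "Patient", "id": "1"}],
            "Encounter": [{"resourceType": "Encounter", "id": "1",
                           "subject": {"reference": "Patient/1"},
                           "period": {"start": "2018-06-01"}}],
            "Coverage": [
                {"resourceType": "Coverage", "id": "1",
                 "beneficiary": {"reference": "Patient/1"},
                 "type": {"coding": [{"system": "urn:omopfhir:payer-type",
                                      "code": "COMMERCIAL"}]},
                 "period": {"start": "2018-01-01", "end": "2018-12-31"}},
                {"resourceType": "Coverage", "id": "2",
                 "beneficiary": {"reference": "Patient/1"},
                 "type": {"coding": [{"system": "urn:omopfhir:payer-type",
                                      "code": "MEDICARE"}]},
                 "period": {"start": "2018-01-01", "end": "2018-12-31"}},
            ],
        }
        db = MendsDb()
        report = import_ndjson(_manifest(tmp_path, resources), db, PayerHierarchy())
        assert report.payers_assigned == 1
        payer = db.conn.execute("SELECT primary_payer FROM encounter").fetchone()[0]
        assert payer == "MEDICARE"
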
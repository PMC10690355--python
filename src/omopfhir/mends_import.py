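"""Load Bulk FHIR NDJSON into a flat surveillance-style relational schema.

The target schema is a documented minimal subset of an ESP-style
surveillance database (patient, encounter, diagnosis, lab_result,
prescription, immunization, social_history), held in an embedded SQLite
database.  The one piece of real modelling here is the coverage
conversion: FHIR Coverage resources carry insurance as *intervals*, while
the surveillance schema wants one primary payer per *encounter*.
:func:`coverage_to_encounter_payer` picks, among the coverages whose
period contains the encounter start date, the payer type ranking highest
in a configurable hierarchy (ties broken by earliest period start).
Period containment is closed-interval; a null end date means open-ended.
"""

from __future__ import annotations

import csv
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence, Union

from .fhir_server import ExportManifest

log = logging.getLogger(__name__)

__all__ = [
    "PayerHierarchy",
    "MendsDb",
    "CoverageInterval",
    "coverage_to_encounter_payer",
    "import_ndjson",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS patient (
    fhir_id TEXT PRIMARY KEY, source_pid TEXT, birth_date TEXT, gender TEXT,
    birth_sex TEXT, race TEXT, ethnicity TEXT, zip TEXT, state TEXT,
    death_date TEXT);
CREATE TABLE IF NOT EXISTS encounter (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, start_date TEXT, end_date TEXT,
    encounter_class TEXT, status TEXT, primary_payer TEXT);
CREATE TABLE IF NOT EXISTS diagnosis (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, encounter_id TEXT, code TEXT,
    code_system TEXT, source_code TEXT, text TEXT, onset_date TEXT,
    abatement_date TEXT);
CREATE TABLE IF NOT EXISTS lab_result (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, encounter_id TEXT, code TEXT,
    code_system TEXT, value REAL, unit TEXT, result_date TEXT);
CREATE TABLE IF NOT EXISTS prescription (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, encounter_id TEXT,
    event_type TEXT, medication_id TEXT, status TEXT, requester TEXT,
    dose_value REAL, dose_unit TEXT, start_date TEXT);
CREATE TABLE IF NOT EXISTS medication (
    fhir_id TEXT PRIMARY KEY, rx_code TEXT, ndc_code TEXT, name TEXT);
CREATE TABLE IF NOT EXISTS immunization (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, cvx_code TEXT, name TEXT,
    admin_date TEXT);
CREATE TABLE IF NOT EXISTS social_history (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, encounter_id TEXT, code TEXT,
    code_system TEXT, value_code TEXT, text TEXT, obs_date TEXT);
CREATE TABLE IF NOT EXISTS coverage (
    fhir_id TEXT PRIMARY KEY, patient_id TEXT, payer_type TEXT,
    start_date TEXT, end_date TEXT);
"""

MENDS_TABLES = (
    "patient", "encounter", "diagnosis", "lab_result", "prescription",
    "medication", "immunization", "social_history", "coverage",
)

_RX_SYSTEM = "http://www.nlm.nih.gov/research/umls/rxnorm"
_NDC_SYSTEM = "http://hl7.org/fhir/sid/ndc"


@dataclass(frozen=True)
class PayerHierarchy:
    """Payer-type codes, highest priority first."""

    codes: tuple[str, ...] = ("MEDICARE", "MEDICAID", "COMMERCIAL", "SELFPAY")

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("payer hierarchy must be non-empty")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("payer hierarchy must not contain duplicates")

    def rank(self, code: Optional[str]) -> int:
        """Lower is higher priority; unknown codes rank below all listed."""
        try:
            return self.codes.index(code)
        except ValueError:
            return len(self.codes)


@dataclass(frozen=True)
class CoverageInterval:
    payer_type: Optional[str]
    start: Optional[date]
    end: Optional[date]  # None = open-ended

    def contains(self, day: date) -> bool:
        if self.start is not None and day < self.start:
            return False
        if self.end is not None and day > self.end:
            return False
        return True


def coverage_to_encounter_payer(
    encounter_start: Optional[date],
    coverages: Sequence[CoverageInterval],
    hierarchy: PayerHierarchy,
) -> Optional[str]:
    """Primary payer for an encounter, or None when nothing overlaps.

    Among coverages whose closed period contains the encounter start date,
    the payer type with the highest hierarchy rank wins; rank ties go to
    the earliest period start (logged), further ties to payer-code order
    for full input-order invariance.
    """
    if encounter_start is None:
        return None
    overlapping = [c for c in coverages if c.contains(encounter_start)]
    if not overlapping:
        return None
    best = min(
        overlapping,
        key=lambda c: (hierarchy.rank(c.payer_type), c.start or date.min,
                       c.payer_type or ""),
    )
    ties = [
        c for c in overlapping
        if hierarchy.rank(c.payer_type) == hierarchy.rank(best.payer_type)
        and c is not best
    ]
    if ties:
        log.info(
            "payer tie at rank %d for encounter on %s; earliest start wins (%s)",
            hierarchy.rank(best.payer_type), encounter_start, best.payer_type,
        )
    return best.payer_type


@dataclass
class LoadReport:
    rows: dict[str, int] = field(default_factory=dict)
    error_lines: int = 0
    payers_assigned: int = 0


class MendsDb:
    """Embedded surveillance database (SQLite file or in-memory)."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def count(self, table: str) -> int:
        if table not in MENDS_TABLES:
            raise KeyError(f"unknown table {table!r}")
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def counts(self) -> dict[str, int]:
        return {t: self.count(t) for t in MENDS_TABLES}

    def orphan_children(self) -> int:
        """Child rows whose patient id is absent from the patient table."""
        n = 0
        for table in ("encounter", "diagnosis", "lab_result", "prescription",
                      "immunization", "social_history", "coverage"):
            n += self.conn.execute(
                f"SELECT COUNT(*) FROM {table} WHERE patient_id IS NOT NULL "
                f"AND patient_id NOT IN (SELECT fhir_id FROM patient)"
            ).fetchone()[0]
        return n

    def dump_csv(self, out_dir: Union[str, Path]) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for table in MENDS_TABLES:
            cur = self.conn.execute(f"SELECT * FROM {table}")
            cols = [d[0] for d in cur.description]
            path = out_dir / f"{table}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(cols)
                writer.writerows(cur.fetchall())
            paths.append(path)
        return paths

    # ------------------------------------------------------- payer assignment

    def assign_primary_payers(self, hierarchy: PayerHierarchy) -> int:
        """Fill encounter.primary_payer from the loaded coverage intervals."""
        coverages_by_patient: dict[str, list[CoverageInterval]] = {}
        for pid, ptype, start, end in self.conn.execute(
            "SELECT patient_id, payer_type, start_date, end_date FROM coverage"
        ):
            coverages_by_patient.setdefault(pid, []).append(
                CoverageInterval(ptype, _to_date(start), _to_date(end))
            )
        assigned = 0
        updates = []
        for fhir_id, pid, start in self.conn.execute(
            "SELECT fhir_id, patient_id, start_date FROM encounter"
        ):
            payer = coverage_to_encounter_payer(
                _to_date(start), coverages_by_patient.get(pid, []), hierarchy
            )
            updates.append((payer, fhir_id))
            if payer is not None:
                assigned += 1
        self.conn.executemany(
            "UPDATE encounter SET primary_payer = ? WHERE fhir_id = ?", updates
        )
        self.conn.commit()
        return assigned


def _to_date(value: Optional[str]) -> Optional[date]:
    if value in (None, ""):
        return None
    return date.fromisoformat(str(value)[:10])


def _ref_id(node: Optional[dict]) -> Optional[str]:
    if not node:
        return None
    ref = node.get("reference", "")
    return ref.split("/", 1)[1] if "/" in ref else ref


def _first_coding(cc: Optional[dict], system: Optional[str] = None) -> tuple[Optional[str], Optional[str], Optional[str]]:
    """(code, system, display) of the first (matching) coding."""
    if not cc:
        return None, None, None
    for coding in cc.get("coding", []):
        if system is None or coding.get("system") == system:
            return coding.get("code"), coding.get("system"), coding.get("display")
    return None, None, None


def import_ndjson(
    manifest: ExportManifest,
    db: MendsDb,
    hierarchy: Optional[PayerHierarchy] = None,
) -> LoadReport:
    """Flatten every exported resource into its surveillance table.

    Unparseable NDJSON lines are logged and skipped (counted in
    ``report.error_lines``).  After loading, encounter primary payers are
    assigned from the coverage intervals when a hierarchy is given.
    """
    report = LoadReport()
    for entry in manifest.output:
        rtype = entry["type"]
        with open(entry["url"], encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    body = json.loads(line)
                except json.JSONDecodeError:
                    report.error_lines += 1
                    log.warning("skipping malformed NDJSON line in %s", entry["url"])
                    continue
                table = _load_resource(db.conn, rtype, body)
                if table:
                    report.rows[table] = report.rows.get(table, 0) + 1
    db.conn.commit()
    if hierarchy is not None:
        report.payers_assigned = db.assign_primary_payers(hierarchy)
    return report


def _load_resource(conn: sqlite3.Connection, rtype: str, body: dict) -> Optional[str]:
    fid = body.get("id")
    if rtype == "Patient":
        ext = {e.get("url", ""): e for e in body.get("extension", [])}
        race = _omb_code(ext.get("http://hl7.org/fhir/us/core/StructureDefinition/us-core-race"))
        eth = _omb_code(ext.get("http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity"))
        sex = (ext.get("http://hl7.org/fhir/us/core/StructureDefinition/us-core-birthsex") or {}).get("valueCode")
        addr = (body.get("address") or [{}])[0]
        source_pid = next(
            (i.get("value") for i in body.get("identifier", [])), None
        )
        conn.execute(
            "INSERT OR REPLACE INTO patient VALUES (?,?,?,?,?,?,?,?,?,?)",
            (fid, source_pid, body.get("birthDate"), body.get("gender"), sex,
             race, eth, addr.get("postalCode"), addr.get("state"),
             body.get("deceasedDateTime")),
        )
        return "patient"
    if rtype == "Encounter":
        period = body.get("period", {})
        conn.execute(
            "INSERT OR REPLACE INTO encounter VALUES (?,?,?,?,?,?,?)",
            (fid, _ref_id(body.get("subject")), period.get("start"),
             period.get("end"), (body.get("class") or {}).get("code"),
             body.get("status"), None),
        )
        return "encounter"
    if rtype == "Condition":
        code, system, _ = _first_coding(body.get("code"))
        source = None
        codings = (body.get("code") or {}).get("coding", [])
        if len(codings) > 1:
            source = codings[1].get("code")
        conn.execute(
            "INSERT OR REPLACE INTO diagnosis VALUES (?,?,?,?,?,?,?,?,?)",
            (fid, _ref_id(body.get("subject")), _ref_id(body.get("encounter")),
             code, system, source, (body.get("code") or {}).get("text"),
             body.get("onsetDateTime"), body.get("abatementDateTime")),
        )
        return "diagnosis"
    if rtype == "Observation":
        categories = {
            c.get("code")
            for cat in body.get("category", [])
            for c in cat.get("coding", [])
        }
        code, system, _ = _first_coding(body.get("code"))
        if "laboratory" in categories:
            vq = body.get("valueQuantity", {})
            conn.execute(
                "INSERT OR REPLACE INTO lab_result VALUES (?,?,?,?,?,?,?,?)",
                (fid, _ref_id(body.get("subject")), _ref_id(body.get("encounter")),
                 code, system, vq.get("value"), vq.get("unit"),
                 body.get("effectiveDateTime")),
            )
            return "lab_result"
        vcc = body.get("valueCodeableConcept")
        value_code, _, _ = _first_coding(vcc)
        text = (vcc or {}).get("text") or body.get("valueString")
        conn.execute(
            "INSERT OR REPLACE INTO social_history VALUES (?,?,?,?,?,?,?,?)",
            (fid, _ref_id(body.get("subject")), _ref_id(body.get("encounter")),
             code, system, value_code, text, body.get("effectiveDateTime")),
        )
        return "social_history"
    if rtype in ("MedicationRequest", "MedicationAdministration", "MedicationDispense"):
        dose_value = dose_unit = None
        if rtype == "MedicationRequest":
            for di in body.get("dosageInstruction", []):
                for dr in di.get("doseAndRate", []):
                    dq = dr.get("doseQuantity")
                    if dq:
                        dose_value, dose_unit = dq.get("value"), dq.get("unit")
        elif rtype == "MedicationAdministration":
            dq = (body.get("dosage") or {}).get("dose")
            if dq:
                dose_value, dose_unit = dq.get("value"), dq.get("unit")
        else:
            dq = body.get("quantity")
            if dq:
                dose_value, dose_unit = dq.get("value"), dq.get("unit")
        start = (body.get("authoredOn") or body.get("effectiveDateTime")
                 or (body.get("effectivePeriod") or {}).get("start")
                 or body.get("whenHandedOver"))
        conn.execute(
            "INSERT OR REPLACE INTO prescription VALUES (?,?,?,?,?,?,?,?,?,?)",
            (fid, _ref_id(body.get("subject")),
             _ref_id(body.get("encounter") or body.get("context")), rtype,
             _ref_id(body.get("medicationReference")), body.get("status"),
             _ref_id(body.get("requester")), dose_value, dose_unit, start),
        )
        return "prescription"
    if rtype == "Medication":
        rx, _, name = _first_coding(body.get("code"), _RX_SYSTEM)
        ndc, _, _ = _first_coding(body.get("code"), _NDC_SYSTEM)
        conn.execute(
            "INSERT OR REPLACE INTO medication VALUES (?,?,?,?)",
            (fid, rx, ndc, name or (body.get("code") or {}).get("text")),
        )
        return "medication"
    if rtype == "Immunization":
        code, _, name = _first_coding(body.get("vaccineCode"))
        conn.execute(
            "INSERT OR REPLACE INTO immunization VALUES (?,?,?,?,?)",
            (fid, _ref_id(body.get("patient")), code, name,
             body.get("occurrenceDateTime")),
        )
        return "immunization"
    if rtype == "Coverage":
        period = body.get("period", {})
        ptype, _, _ = _first_coding(body.get("type"))
        conn.execute(
            "INSERT OR REPLACE INTO coverage VALUES (?,?,?,?,?)",
            (fid, _ref_id(body.get("beneficiary")), ptype,
             period.get("start"), period.get("end")),
        )
        return "coverage"
    log.warning("no surveillance mapping for resourceType %s; line ignored", rtype)
    return None


def _omb_code(ext: Optional[dict]) -> Optional[str]:
    if not ext:
        return None
    for sub in ext.get("extension", []):
        if sub.get("url") == "ombCategory":
            return (sub.get("valueCoding") or {}).get("code")
    return None
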
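"""OMOP CDM v5.3 table store, cohort filter, and chunked OMOP JSON export.

The extraction contract: every row of an OMOP JSON document carries all the
data one FHIR resource needs, so the downstream builder never queries back
into the store.  That means per-table shaping joins happen here —
PERSON is left-joined with DEATH and LOCATION, DRUG_EXPOSURE with
DRUG_STRENGTH and the visit-level provider, and every ``*_concept_id``
column is resolved against CONCEPT into sibling ``*_code`` / ``*_name`` /
``*_vocabulary`` fields.  Smoking-survey OBSERVATION rows are pre-aggregated
into one row per encounter (see :mod:`omopfhir.smoking`).

Output documents have the single-key shape ``{"<table>": [row, ...]}`` and
are partitioned so every document holds exactly ``chunk_size`` rows except
the last; the partition is a pure re-chunking, so concatenating all
documents reproduces the shaped, cohort-filtered table for any chunk size.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .smoking import SMOKING_QUESTIONS, SmokingResponse, render_smoking_source_value

log = logging.getLogger(__name__)

__all__ = [
    "OMOP_TABLES",
    "CohortCriteria",
    "ExtractionConfig",
    "OmopJsonDocument",
    "OmopStore",
    "load_omop",
]

#: The 11 OMOP CDM v5.3 tables the pipeline consumes.
OMOP_TABLES = (
    "person",
    "location",
    "death",
    "visit_occurrence",
    "condition_occurrence",
    "payer_plan_period",
    "observation",
    "measurement",
    "drug_exposure",
    "drug_strength",
    "concept",
)

#: Primary key column per table (drug_strength has a composite key).
PRIMARY_KEYS: dict[str, Union[str, tuple[str, ...]]] = {
    "person": "person_id",
    "location": "location_id",
    "death": "person_id",
    "visit_occurrence": "visit_occurrence_id",
    "condition_occurrence": "condition_occurrence_id",
    "payer_plan_period": "payer_plan_period_id",
    "observation": "observation_id",
    "measurement": "measurement_id",
    "drug_exposure": "drug_exposure_id",
    "drug_strength": ("drug_concept_id", "ingredient_concept_id"),
    "concept": "concept_id",
}

# Expected columns per table (OMOP v5.3 subset used by the pipeline).
# Unknown columns in an input CSV are warned about and ignored.
EXPECTED_COLUMNS: dict[str, tuple[str, ...]] = {
    "person": (
        "person_id", "gender_concept_id", "year_of_birth", "month_of_birth",
        "day_of_birth", "birth_datetime", "race_concept_id",
        "ethnicity_concept_id", "location_id", "provider_id", "care_site_id",
        "person_source_value", "gender_source_value", "race_source_value",
        "ethnicity_source_value",
    ),
    "location": ("location_id", "address_1", "city", "state", "zip", "county"),
    "death": (
        "person_id", "death_date", "death_datetime", "death_type_concept_id",
        "cause_concept_id",
    ),
    "visit_occurrence": (
        "visit_occurrence_id", "person_id", "visit_concept_id",
        "visit_start_date", "visit_start_datetime", "visit_end_date",
        "visit_end_datetime", "visit_type_concept_id", "provider_id",
        "care_site_id", "visit_source_value",
    ),
    "condition_occurrence": (
        "condition_occurrence_id", "person_id", "condition_concept_id",
        "condition_start_date", "condition_start_datetime",
        "condition_end_date", "condition_end_datetime",
        "condition_type_concept_id", "stop_reason", "provider_id",
        "visit_occurrence_id", "condition_source_value",
        "condition_source_concept_id", "condition_status_concept_id",
    ),
    "payer_plan_period": (
        "payer_plan_period_id", "person_id", "payer_plan_period_start_date",
        "payer_plan_period_end_date", "payer_concept_id", "payer_source_value",
        "plan_concept_id", "plan_source_value",
    ),
    "observation": (
        "observation_id", "person_id", "observation_concept_id",
        "observation_date", "observation_datetime",
        "observation_type_concept_id", "value_as_number", "value_as_string",
        "value_as_concept_id", "qualifier_concept_id", "unit_concept_id",
        "provider_id", "visit_occurrence_id", "observation_source_value",
        "observation_source_concept_id", "unit_source_value",
    ),
    "measurement": (
        "measurement_id", "person_id", "measurement_concept_id",
        "measurement_date", "measurement_datetime",
        "measurement_type_concept_id", "operator_concept_id",
        "value_as_number", "value_as_concept_id", "unit_concept_id",
        "range_low", "range_high", "provider_id", "visit_occurrence_id",
        "measurement_source_value", "measurement_source_concept_id",
        "unit_source_value",
    ),
    "drug_exposure": (
        "drug_exposure_id", "person_id", "drug_concept_id",
        "drug_exposure_start_date", "drug_exposure_start_datetime",
        "drug_exposure_end_date", "drug_exposure_end_datetime",
        "verbatim_end_date", "drug_type_concept_id", "stop_reason", "refills",
        "quantity", "days_supply", "sig", "route_concept_id", "lot_number",
        "provider_id", "visit_occurrence_id", "drug_source_value",
        "drug_source_concept_id", "route_source_value", "dose_unit_source_value",
    ),
    "drug_strength": (
        "drug_concept_id", "ingredient_concept_id", "amount_value",
        "amount_unit_concept_id", "numerator_value",
        "numerator_unit_concept_id", "denominator_value",
        "denominator_unit_concept_id",
    ),
    "concept": (
        "concept_id", "concept_name", "domain_id", "vocabulary_id",
        "concept_class_id", "standard_concept", "concept_code",
        "valid_start_date", "valid_end_date", "invalid_reason",
    ),
}

# CONCEPT columns that end in _id but hold strings, not integer keys
_STRING_ID_COLUMNS = {"vocabulary_id", "domain_id", "concept_class_id"}

_FLOAT_COLUMNS = {
    "value_as_number", "quantity", "days_supply", "refills", "range_low",
    "range_high", "amount_value", "numerator_value", "denominator_value",
}

#: Default OMOP standard visit concepts counted as "clinical" visits:
#: 9201 inpatient, 9202 outpatient, 9203 emergency department.
DEFAULT_CLINICAL_VISIT_CLASSES = frozenset({9201, 9202, 9203})


@dataclass
class CohortCriteria:
    """The three cohort inclusion criteria.

    A person is in-cohort iff they have at least one clinical visit
    (allowed class) starting on/after ``min_visit_date``, are at least
    ``min_age_years`` old at ``as_of_date``, and have a linked LOCATION
    row with a 5-digit zip and a non-empty state.
    """

    min_visit_date: date = date(2017, 1, 1)
    allowed_visit_classes: frozenset[int] = DEFAULT_CLINICAL_VISIT_CLASSES
    min_age_years: int = 2
    require_zip5_and_state: bool = True
    as_of_date: Optional[date] = None  # None -> today at filter time

    def __post_init__(self) -> None:
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be >= 0")
        self.allowed_visit_classes = frozenset(int(c) for c in self.allowed_visit_classes)
        if self.as_of_date is not None and self.as_of_date < self.min_visit_date:
            raise ValueError("as_of_date must be on or after min_visit_date")


@dataclass
class ExtractionConfig:
    """Chunking and table selection for OMOP JSON export."""

    chunk_size: int = 1000
    tables: tuple[str, ...] = (
        "person", "visit_occurrence", "condition_occurrence",
        "payer_plan_period", "observation", "measurement", "drug_exposure",
    )
    output_dir: Optional[Path] = None
    smoking_questions: tuple[str, ...] = SMOKING_QUESTIONS
    # answerless free-text entries recorded alongside the survey (rendered
    # without a colon); matched verbatim on observation_source_value
    smoking_freetext_values: tuple[str, ...] = (
        "Nicotine dependence, cigarettes, uncomplicated",
    )
    # fixed UTC offset appended to datetimes that lack one
    utc_offset: str = "+00:00"

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass
class OmopJsonDocument:
    """Single-key JSON document ``{table: [row, ...]}``; one transform unit."""

    table: str
    rows: list[dict]
    index: int = 0

    def to_dict(self) -> dict:
        return {self.table: self.rows}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, indent=1)

    @property
    def filename(self) -> str:
        return f"{self.table}_{self.index}.json"


def _zip5(zip_value: Optional[str]) -> Optional[str]:
    """Normalize a zip to exactly 5 digits; ZIP+4 is truncated; else None."""
    if zip_value is None:
        return None
    z = str(zip_value).strip()
    if re.fullmatch(r"\d{5}-\d{4}", z):
        z = z[:5]
    return z if re.fullmatch(r"\d{5}", z) else None


def _age_years(birth: date, as_of: date) -> int:
    years = as_of.year - birth.year
    if (as_of.month, as_of.day) < (birth.month, birth.day):
        years -= 1
    return years


def _parse_date(value) -> Optional[date]:
    if value in (None, ""):
        return None
    return date.fromisoformat(str(value)[:10])


class OmopStore:
    """In-memory queryable store over the 11 loaded OMOP tables."""

    def __init__(self, tables: dict[str, pd.DataFrame]):
        self.tables = tables
        self._concept_index: dict[int, dict] = {}
        if "concept" in tables:
            cdf = tables["concept"]
            self._concept_index = {
                int(r["concept_id"]): {
                    "concept_name": r["concept_name"],
                    "vocabulary_id": r["vocabulary_id"],
                    "concept_code": r["concept_code"],
                    "domain_id": r.get("domain_id"),
                    "standard_concept": r.get("standard_concept"),
                }
                for r in cdf.to_dict("records")
            }

    # -- basic queries --------------------------------------------------------

    def table(self, name: str) -> pd.DataFrame:
        if name not in self.tables:
            raise KeyError(f"table {name!r} not loaded")
        return self.tables[name]

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables.items()}

    def get_concept(self, concept_id: Optional[int]) -> Optional[dict]:
        if concept_id is None:
            return None
        return self._concept_index.get(int(concept_id))

    def concept_exists(self, vocabulary_id: str, code: str) -> bool:
        """Used by validation as the stand-in terminology source."""
        for c in self._concept_index.values():
            if c["vocabulary_id"] == vocabulary_id and str(c["concept_code"]) == str(code):
                return True
        return False

    def build_code_index(self) -> set[tuple[str, str]]:
        return {
            (c["vocabulary_id"], str(c["concept_code"]))
            for c in self._concept_index.values()
        }

    # -- cohort ---------------------------------------------------------------

    def apply_cohort_filter(self, criteria: CohortCriteria) -> set[int]:
        """person_ids satisfying all three MENDS-style inclusion criteria."""
        as_of = criteria.as_of_date or date.today()

        visits = self.table("visit_occurrence")
        ok_visits = visits[
            visits["visit_concept_id"].isin(criteria.allowed_visit_classes)
            & (visits["visit_start_date"].map(_parse_date) >= criteria.min_visit_date)
        ]
        persons_with_visit = {int(p) for p in ok_visits["person_id"].dropna()}

        result: set[int] = set()
        locations = {
            int(r["location_id"]): r for r in self.table("location").to_dict("records")
            if r.get("location_id") not in (None, "")
        }
        for row in self.table("person").to_dict("records"):
            pid = int(row["person_id"])
            if pid not in persons_with_visit:
                continue
            birth = self._birth_date(row)
            if birth is None or _age_years(birth, as_of) < criteria.min_age_years:
                continue
            if criteria.require_zip5_and_state:
                loc = locations.get(_as_int(row.get("location_id")) or -1)
                if loc is None:
                    continue
                state = str(loc.get("state") or "").strip()
                if _zip5(loc.get("zip")) is None or not state:
                    continue
            result.add(pid)
        return result

    @staticmethod
    def _birth_date(person_row: dict) -> Optional[date]:
        bd = person_row.get("birth_datetime")
        if bd not in (None, ""):
            return _parse_date(bd)
        y = _as_int(person_row.get("year_of_birth"))
        if y is None:
            return None
        m = _as_int(person_row.get("month_of_birth")) or 1
        d = _as_int(person_row.get("day_of_birth")) or 1
        return date(y, m, d)

    # -- shaping and extraction ----------------------------------------------

    def shaped_table(
        self,
        table: str,
        cohort: set[int],
        config: Optional[ExtractionConfig] = None,
    ) -> list[dict]:
        """Cohort-filtered rows with all per-table joins applied, pk-ascending."""
        config = config or ExtractionConfig()
        if table not in self.tables:
            raise KeyError(f"table {table!r} not loaded")

        if table == "person":
            rows = self._shape_person(cohort)
        elif table == "drug_exposure":
            rows = self._shape_drug_exposure(cohort)
        elif table == "observation":
            rows = self._shape_observation(cohort, config)
        else:
            rows = [
                r for r in self.table(table).to_dict("records")
                if _as_int(r.get("person_id")) in cohort
            ]
        for row in rows:
            self._resolve_concept_columns(row)
        pk = PRIMARY_KEYS[table]
        key = pk if isinstance(pk, str) else pk[0]
        rows.sort(key=lambda r: _as_int(r.get(key)) or 0)
        return [_jsonify_row(r) for r in rows]

    def _shape_person(self, cohort: set[int]) -> list[dict]:
        deaths = {
            _as_int(r["person_id"]): r for r in self.table("death").to_dict("records")
        }
        locations = {
            _as_int(r["location_id"]): r
            for r in self.table("location").to_dict("records")
        }
        rows = []
        for r in self.table("person").to_dict("records"):
            pid = _as_int(r.get("person_id"))
            if pid not in cohort:
                continue
            row = dict(r)
            death = deaths.get(pid)
            # LEFT JOIN semantics: death_date present (null) for living persons
            row["death_date"] = (death or {}).get("death_date") or None
            row["death_datetime"] = (death or {}).get("death_datetime") or None
            loc = locations.get(_as_int(r.get("location_id"))) or {}
            row["zip"] = _zip5(loc.get("zip"))
            row["state"] = (str(loc.get("state")).strip() or None) if loc.get("state") else None
            row["city"] = loc.get("city") or None
            rows.append(row)
        return rows

    def _shape_drug_exposure(self, cohort: set[int]) -> list[dict]:
        # first DRUG_STRENGTH ingredient row per drug_concept_id
        strength: dict[int, dict] = {}
        for r in self.table("drug_strength").to_dict("records"):
            did = _as_int(r.get("drug_concept_id"))
            if did is not None and did not in strength:
                strength[did] = r
        visit_provider = {
            _as_int(r["visit_occurrence_id"]): _as_int(r.get("provider_id"))
            for r in self.table("visit_occurrence").to_dict("records")
        }
        rows = []
        for r in self.table("drug_exposure").to_dict("records"):
            if _as_int(r.get("person_id")) not in cohort:
                continue
            row = dict(r)
            s = strength.get(_as_int(r.get("drug_concept_id")))
            row["amount_value"] = s.get("amount_value") if s else None
            row["amount_unit_concept_id"] = _as_int(s.get("amount_unit_concept_id")) if s else None
            row["visit_provider_id"] = visit_provider.get(_as_int(r.get("visit_occurrence_id")))
            rows.append(row)
        return rows

    def _shape_observation(self, cohort: set[int], config: ExtractionConfig) -> list[dict]:
        """Aggregate smoking-survey rows into one row per encounter."""
        questions = set(config.smoking_questions)
        freetext = set(config.smoking_freetext_values)
        plain: list[dict] = []
        surveys: dict[tuple, list[dict]] = {}
        for r in self.table("observation").to_dict("records"):
            if _as_int(r.get("person_id")) not in cohort:
                continue
            src = str(r.get("observation_source_value") or "")
            question = src.split(":", 1)[0]
            if question in questions or src in freetext:
                key = (_as_int(r["person_id"]), _as_int(r.get("visit_occurrence_id")))
                surveys.setdefault(key, []).append(dict(r))
            else:
                plain.append(dict(r))

        for (pid, vid), group in surveys.items():
            responses = []
            for g in group:
                src = str(g.get("observation_source_value") or "")
                q = src.split(":", 1)[0]
                answer = g.get("value_as_string")
                responses.append(
                    SmokingResponse(question=q, answer=answer if answer not in (None, "") else None)
                )
            group.sort(key=lambda g: _as_int(g.get("observation_id")) or 0)
            base = dict(group[0])
            base["observation_source_value"] = render_smoking_source_value(responses)
            base["smoking_responses"] = [
                {"question": r.question, "answer": r.answer}
                for r in sorted(responses, key=lambda r: (r.question, r.answer or ""))
            ]
            base["is_smoking_aggregate"] = True
            base["value_as_string"] = None
            plain.append(base)
        return plain

    def _resolve_concept_columns(self, row: dict) -> None:
        """Attach *_code/*_name/*_vocabulary siblings for *_concept_id keys."""
        for col in [c for c in row if c.endswith("_concept_id")]:
            base = col[: -len("_concept_id")]
            cid = _as_int(row[col])
            concept = self.get_concept(cid) if cid else None
            row[f"{base}_code"] = concept["concept_code"] if concept else None
            row[f"{base}_name"] = concept["concept_name"] if concept else None
            row[f"{base}_vocabulary"] = concept["vocabulary_id"] if concept else None

    def extract_table_json(
        self,
        table: str,
        config: ExtractionConfig,
        cohort: set[int],
    ) -> list[OmopJsonDocument]:
        """Partition the shaped table into CHUNKSIZE-row documents."""
        rows = self.shaped_table(table, cohort, config)
        if not rows:
            return []
        n_chunks = math.ceil(len(rows) / config.chunk_size)
        return [
            OmopJsonDocument(
                table=table,
                rows=rows[i * config.chunk_size : (i + 1) * config.chunk_size],
                index=i,
            )
            for i in range(n_chunks)
        ]

    def extract_all(
        self, config: ExtractionConfig, cohort: set[int]
    ) -> dict[str, list[OmopJsonDocument]]:
        return {t: self.extract_table_json(t, config, cohort) for t in config.tables}


def write_documents(docs: Iterable[OmopJsonDocument], out_dir: Union[str, Path]) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in docs:
        path = out_dir / doc.filename
        path.write_text(doc.to_json(), encoding="utf-8")
        paths.append(path)
    return paths


def read_document(path: Union[str, Path]) -> OmopJsonDocument:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if len(doc) != 1:
        raise ValueError(f"{path}: OMOP JSON must have exactly one top-level key")
    table, rows = next(iter(doc.items()))
    stem = Path(path).stem
    idx = int(stem.rsplit("_", 1)[1]) if stem.rsplit("_", 1)[-1].isdigit() else 0
    return OmopJsonDocument(table=table, rows=rows, index=idx)


def _as_int(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    return int(value)


def _jsonify_row(row: dict) -> dict:
    out = {}
    for k, v in row.items():
        if v is None or v == "":
            out[k] = None
        elif isinstance(v, float):
            out[k] = None if math.isnan(v) else v
        elif pd.api.types.is_scalar(v) and pd.isna(v):
            out[k] = None
        elif hasattr(v, "item"):  # numpy scalar
            out[k] = v.item()
        else:
            out[k] = v
    return out


def load_omop(csv_dir: Union[str, Path], tables: Iterable[str] = OMOP_TABLES) -> OmopStore:
    """Load OMOP CSVs (one per table, any filename case) into a store.

    A missing table is fatal; an unknown column is warned about and
    dropped; a duplicated primary key is fatal, naming the key.
    """
    csv_dir = Path(csv_dir)
    available = {p.stem.lower(): p for p in csv_dir.glob("*.csv")}
    frames: dict[str, pd.DataFrame] = {}
    for table in tables:
        path = available.get(table)
        if path is None:
            raise FileNotFoundError(f"mandatory OMOP table {table!r}: no CSV in {csv_dir}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        expected = set(EXPECTED_COLUMNS[table])
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            log.warning("table %s: ignoring unknown columns %s", table, unknown)
            df = df.drop(columns=unknown)
        df = df.replace({"": None})
        for col in df.columns:
            if col in _STRING_ID_COLUMNS:
                continue
            if col.endswith("_id") and not col.endswith("_source_id"):
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
            elif col in _FLOAT_COLUMNS:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        _check_primary_key(table, df)
        frames[table] = df
    store = OmopStore(frames)
    log.info("loaded OMOP store: %s", store.row_counts())
    return store


def _check_primary_key(table: str, df: pd.DataFrame) -> None:
    pk = PRIMARY_KEYS[table]
    cols = [pk] if isinstance(pk, str) else list(pk)
    if not all(c in df.columns for c in cols) or df.empty:
        return
    dupes = df[df.duplicated(subset=cols, keep=False)]
    if not dupes.empty:
        first = dupes.iloc[0][cols[0]]
        raise ValueError(
            f"table {table!r}: duplicated primary key {'+'.join(cols)} "
            f"(e.g. {cols[0]}={first})"
        )
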
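"""End-to-end orchestration: extract -> transform -> (validate) -> import
-> export -> load, with a per-stage run manifest.

Each stage is independently callable (the CLI exposes one subcommand per
stage); :func:`run_pipeline` chains them and records input/output counts
and durations.  Any stage failure halts the run; the partial manifest is
attached to the raised :class:`PipelineError`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Union

from .fhir_server import ResourceStore, export_bulk, import_bundles
from .mends_import import MendsDb, PayerHierarchy, import_ndjson
from .omop_store import (
    CohortCriteria,
    ExtractionConfig,
    OmopStore,
    load_omop,
    write_documents,
)
from .terminology import TerminologyService, default_maps_dir
from .transform import ResourceTransformer, registry_fhir_types
from .validate import ValidationReport, Validator

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

#: FHIR types requested at export, in a fixed order.
EXPORT_TYPES = (
    "Patient", "Encounter", "Condition", "Coverage", "Observation",
    "MedicationRequest", "MedicationAdministration", "MedicationDispense",
    "Medication", "Immunization",
)


@dataclass
class PipelineConfig:
    omop_dir: Path
    out_dir: Path
    maps_dir: Optional[Path] = None  # None -> the maps shipped in-package
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    validate: bool = True
    hierarchy: PayerHierarchy = field(default_factory=PayerHierarchy)
    seed: int = 0

    def __post_init__(self) -> None:
        self.omop_dir = Path(self.omop_dir)
        self.out_dir = Path(self.out_dir)
        if self.extraction.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {"omop_dir", "out_dir", "maps_dir", "validate", "seed",
                 "chunk_size", "payer_hierarchy", "min_visit_date",
                 "min_age_years", "as_of_date"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        criteria = CohortCriteria(
            min_visit_date=_opt_date(doc.get("min_visit_date")) or date(2017, 1, 1),
            min_age_years=int(doc.get("min_age_years", 2)),
            as_of_date=_opt_date(doc.get("as_of_date")),
        )
        extraction = ExtractionConfig(chunk_size=int(doc.get("chunk_size", 1000)))
        hierarchy = (
            PayerHierarchy(tuple(doc["payer_hierarchy"]))
            if doc.get("payer_hierarchy") else PayerHierarchy()
        )
        return cls(
            omop_dir=Path(doc["omop_dir"]),
            out_dir=Path(doc["out_dir"]),
            maps_dir=Path(doc["maps_dir"]) if doc.get("maps_dir") else None,
            criteria=criteria,
            extraction=extraction,
            validate=bool(doc.get("validate", True)),
            hierarchy=hierarchy,
            seed=int(doc.get("seed", 0)),
        )


class PipelineError(RuntimeError):
    def __init__(self, message: str, manifest: dict):
        super().__init__(message)
        self.manifest = manifest


@dataclass
class PipelineResult:
    manifest: dict
    store: OmopStore
    server: ResourceStore
    db: MendsDb
    validation: Optional[ValidationReport] = None


def build_terminology(maps_dir: Optional[Path] = None) -> TerminologyService:
    service = TerminologyService()
    service.load_map_dir(maps_dir or default_maps_dir())
    return service


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    manifest: dict = {"seed": config.seed, "stages": []}
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        entry = {"name": name, "status": "running", "counts": {}, "duration_s": None}
        manifest["stages"].append(entry)
        return entry, time.perf_counter()

    def finish(entry, t0, **counts):
        entry["counts"].update(counts)
        entry["duration_s"] = round(time.perf_counter() - t0, 3)
        entry["status"] = "ok"

    def fail(entry, t0, exc):
        entry["status"] = "failed"
        entry["error"] = str(exc)
        entry["duration_s"] = round(time.perf_counter() - t0, 3)
        _write_manifest(manifest, out)
        raise PipelineError(f"stage {entry['name']} failed: {exc}", manifest) from exc

    # 1.0 extract
    entry, t0 = stage("extract")
    try:
        store = load_omop(config.omop_dir)
        cohort = store.apply_cohort_filter(config.criteria)
        documents = store.extract_all(config.extraction, cohort)
        json_dir = out / "omop_json"
        for docs in documents.values():
            write_documents(docs, json_dir)
        finish(
            entry, t0,
            cohort_size=len(cohort),
            table_rows={t: sum(len(d.rows) for d in docs)
                        for t, docs in documents.items()},
            documents=sum(len(d) for d in documents.values()),
        )
    except Exception as exc:  # noqa: BLE001 - halt with partial manifest
        fail(entry, t0, exc)

    # 2.0 transform
    entry, t0 = stage("transform")
    try:
        terminology = build_terminology(config.maps_dir)
        transformer = ResourceTransformer(terminology)
        bundles = []
        bundles_dir = out / "bundles"
        bundles_dir.mkdir(parents=True, exist_ok=True)
        for table in config.extraction.tables:
            for doc in documents[table]:
                bundle = transformer.transform_document(doc)
                bundles.append(bundle)
                (bundles_dir / f"{table}_{doc.index}.bundle.json").write_text(
                    json.dumps(bundle.to_fhir(), ensure_ascii=False, indent=1),
                    encoding="utf-8",
                )
        by_type: dict[str, int] = {}
        for b in bundles:
            for e in b.entries:
                rt = e["resource"]["resourceType"]
                by_type[rt] = by_type.get(rt, 0) + 1
        finish(entry, t0, bundles=len(bundles), resources=by_type)
    except Exception as exc:  # noqa: BLE001
        fail(entry, t0, exc)

    # 3.0 validate (optional)
    validation = None
    entry, t0 = stage("validate")
    if not config.validate:
        entry["status"] = "skipped"
        entry["duration_s"] = 0.0
    else:
        try:
            validator = Validator.from_store(terminology, store)
            reports = (
                validator.validate_resource(e["resource"])
                for b in bundles for e in b.entries
            )
            validation = Validator.summarize(reports)
            (out / "validation.json").write_text(
                json.dumps(validation.to_dict(), indent=1), encoding="utf-8"
            )
            finish(
                entry, t0,
                resources_checked=validation.resources_checked,
                resources_with_error=validation.resources_with_error,
                non_compliance_rate=validation.non_compliance_rate,
            )
        except Exception as exc:  # noqa: BLE001
            fail(entry, t0, exc)

    # 4.0 import (full refresh, server-generated ids)
    entry, t0 = stage("import")
    try:
        server = ResourceStore()
        import_report = import_bundles(bundles, server)
        finish(entry, t0, imported=import_report.imported,
               unresolved_references=len(import_report.unresolved_references))
    except Exception as exc:  # noqa: BLE001
        fail(entry, t0, exc)

    # 5.0 export
    entry, t0 = stage("export")
    try:
        present = [t for t in EXPORT_TYPES if t in registry_fhir_types()]
        export_manifest = export_bulk(server, present, out / "ndjson")
        finish(entry, t0,
               exported={e["type"]: e["count"] for e in export_manifest.output})
    except Exception as exc:  # noqa: BLE001
        fail(entry, t0, exc)

    # 6.0 load into the surveillance database
    entry, t0 = stage("load")
    try:
        db_path = out / "mends.db"
        if db_path.exists():  # full refresh semantics extend to the DB file
            db_path.unlink()
        db = MendsDb(db_path)
        load_report = import_ndjson(export_manifest, db, config.hierarchy)
        finish(entry, t0, loaded=load_report.rows,
               error_lines=load_report.error_lines,
               payers_assigned=load_report.payers_assigned)
    except Exception as exc:  # noqa: BLE001
        fail(entry, t0, exc)

    _write_manifest(manifest, out)
    return PipelineResult(
        manifest=manifest, store=store, server=server, db=db, validation=validation
    )


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )


def _opt_date(value) -> Optional[date]:
    if value in (None, ""):
        return None
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))
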
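"""In-process emulation of a FHIR server's $import and Bulk $export.

The import contract mirrors how a bulk-load-oriented FHIR server behaves:
no referential integrity check at import time; fresh server-generated
resource ids (monotonically increasing integers per type, deterministic
given input order); ``urn:uuid`` references rewritten to ``Type/id`` in a
second pass where the target was seen in the same import, left as-is and
logged otherwise; a full content refresh on every import.

"Asynchronous" bulk export is modelled as a synchronous call that writes
one NDJSON file per requested resource type and returns a manifest in the
shape of a Bulk FHIR status response.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .transform import Bundle

log = logging.getLogger(__name__)

__all__ = ["ResourceStore", "ExportManifest", "import_bundles", "export_bulk"]


@dataclass
class ImportReport:
    imported: dict[str, int] = field(default_factory=dict)
    unresolved_references: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.imported.values())


@dataclass
class ExportManifest:
    """Bulk-export status response: one output entry per resource type."""

    request_time: str
    output: list[dict] = field(default_factory=list)  # {type, url, count}

    def to_dict(self) -> dict:
        return {"transactionTime": self.request_time, "output": self.output}

    def count_for(self, resource_type: str) -> int:
        for entry in self.output:
            if entry["type"] == resource_type:
                return entry["count"]
        return 0


class ResourceStore:
    """Emulated server content keyed by (resourceType, server id)."""

    def __init__(self) -> None:
        self.resources: dict[tuple[str, int], dict] = {}
        self.id_counters: dict[str, int] = {}
        self.import_errors: list[str] = []

    def clear(self) -> None:
        self.resources.clear()
        self.id_counters.clear()
        self.import_errors.clear()

    def next_id(self, resource_type: str) -> int:
        self.id_counters[resource_type] = self.id_counters.get(resource_type, 0) + 1
        return self.id_counters[resource_type]

    def put(self, resource_type: str, server_id: int, body: dict) -> None:
        key = (resource_type, server_id)
        if key in self.resources:
            raise KeyError(f"duplicate server id {resource_type}/{server_id}")
        self.resources[key] = body

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rtype, _ in self.resources:
            out[rtype] = out.get(rtype, 0) + 1
        return out

    def resource_types(self) -> set[str]:
        return {rtype for rtype, _ in self.resources}

    def all_of_type(self, resource_type: str) -> list[tuple[int, dict]]:
        return sorted(
            (sid, body) for (rtype, sid), body in self.resources.items()
            if rtype == resource_type
        )


def _rewrite_references(node, mapping: dict[str, str], unresolved: list[str]):
    if isinstance(node, dict):
        out = {}
        for key, value in node.items():
            if key == "reference" and isinstance(value, str) and value.startswith("urn:uuid:"):
                if value in mapping:
                    out[key] = mapping[value]
                else:
                    unresolved.append(value)
                    out[key] = value  # dangling reference kept as-is
            else:
                out[key] = _rewrite_references(value, mapping, unresolved)
        return out
    if isinstance(node, list):
        return [_rewrite_references(v, mapping, unresolved) for v in node]
    return node


def import_bundles(bundles: Iterable[Bundle], store: ResourceStore) -> ImportReport:
    """$import a stream of Bundles into the store (full refresh).

    Two passes: first assign fresh server ids to every entry (building the
    urn:uuid -> Type/id map), then rewrite references.  Unresolvable
    references are logged and left untouched — never fatal.
    """
    store.clear()
    report = ImportReport()

    staged: list[tuple[str, int, str, dict]] = []
    mapping: dict[str, str] = {}
    for bundle in bundles:
        entries = bundle.entries if isinstance(bundle, Bundle) else bundle.get("entry", [])
        for entry in entries:
            body = entry["resource"]
            rtype = body["resourceType"]
            server_id = store.next_id(rtype)
            full_url = entry.get("fullUrl")
            if full_url:
                mapping[full_url] = f"{rtype}/{server_id}"
            staged.append((rtype, server_id, full_url or "", body))

    for rtype, server_id, _, body in staged:
        unresolved: list[str] = []
        rewritten = _rewrite_references(body, mapping, unresolved)
        rewritten = dict(rewritten)
        rewritten["id"] = str(server_id)
        store.put(rtype, server_id, rewritten)
        report.imported[rtype] = report.imported.get(rtype, 0) + 1
        for ref in unresolved:
            msg = f"{rtype}/{server_id}: unresolved reference {ref}"
            store.import_errors.append(msg)
            report.unresolved_references.append(ref)
            log.warning("import: %s", msg)
    return report


def export_bulk(
    store: ResourceStore,
    types: Iterable[str],
    out_dir: Union[str, Path],
    request_time: str = "1970-01-01T00:00:00+00:00",
) -> ExportManifest:
    """Bulk $export: one NDJSON file per requested type, all instances.

    An unknown type (never imported and not a known FHIR type in the
    store) raises, listing the valid types.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    types = list(types)
    valid = store.resource_types()
    unknown = [t for t in types if t not in valid]
    if unknown:
        # a requested type with zero instances is only valid if the store
        # knows nothing at all (empty export) — otherwise flag the typo
        if valid:
            known_empty = [t for t in unknown if t in _KNOWN_TYPES]
            bad = [t for t in unknown if t not in _KNOWN_TYPES]
            if bad:
                raise KeyError(
                    f"unknown resource type(s) {bad}; valid types: {sorted(valid | _KNOWN_TYPES)}"
                )
            unknown = known_empty

    manifest = ExportManifest(request_time=request_time)
    for rtype in types:
        path = out_dir / f"{rtype}.ndjson"
        count = 0
        with open(path, "w", encoding="utf-8") as fh:
            for _, body in store.all_of_type(rtype):
                fh.write(json.dumps(body, ensure_ascii=False) + "\n")
                count += 1
        manifest.output.append({"type": rtype, "url": str(path), "count": count})
    return manifest


_KNOWN_TYPES = {
    "Patient", "Encounter", "Condition", "Coverage", "Observation",
    "MedicationRequest", "MedicationAdministration", "MedicationDispense",
    "Medication", "Immunization",
}
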
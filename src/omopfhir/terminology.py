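"""Local terminology translation for the OMOP-to-FHIR pipeline.

All code translation is performed against local FHIR R4 ConceptMap JSON
files plus the loaded OMOP CONCEPT table; no remote terminology service is
ever contacted.  Two translation routes exist:

* :meth:`TerminologyService.translate` — ConceptMap lookup keyed by a
  stringified OMOP ``concept_id`` (the source codes of the shipped maps are
  concept_ids, mirroring how the pipeline's demographic maps are authored).
* :func:`concept_coding` — direct CONCEPT-table resolution of a concept_id
  into a ``Coding`` whose ``system`` comes from the vocabulary registry.

An unmatched translation is always an explicit :data:`UNMATCHED` result,
never a silent empty list: downstream builders decide whether to omit the
element or fall back to a text-only CodeableConcept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "Coding",
    "CodeableConcept",
    "ConceptMap",
    "ConceptMapError",
    "Unmatched",
    "UNMATCHED",
    "DEFAULT_SYSTEM_REGISTRY",
    "UNKNOWN_SYSTEM",
    "TerminologyService",
    "load_concept_map",
    "concept_coding",
]


@dataclass(frozen=True)
class Coding:
    """One (system, code, display) triple."""

    system: str
    code: str
    display: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code and not self.system:
            raise ValueError("Coding.system must be non-empty when a code is present")

    def to_fhir(self) -> dict:
        out = {"system": self.system, "code": self.code}
        if self.display is not None:
            out["display"] = self.display
        return out


@dataclass
class CodeableConcept:
    """Ordered codings plus an optional free-text label.

    The coding list may be empty only when ``text`` is non-empty — a fully
    empty concept carries no information and is rejected.
    """

    coding: list[Coding] = field(default_factory=list)
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.coding and not self.text:
            raise ValueError("CodeableConcept requires at least one coding or text")

    def to_fhir(self) -> dict:
        out: dict = {}
        if self.coding:
            out["coding"] = [c.to_fhir() for c in self.coding]
        if self.text is not None:
            out["text"] = self.text
        return out


class Unmatched:
    """Sentinel for a translation with no target (singleton)."""

    _instance: Optional["Unmatched"] = None

    def __new__(cls) -> "Unmatched":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNMATCHED"

    def __bool__(self) -> bool:
        return False


UNMATCHED = Unmatched()

TranslateResult = Union[list[Coding], Unmatched]


class ConceptMapError(ValueError):
    """Raised for malformed or duplicated ConceptMap content."""


@dataclass
class ConceptMap:
    """Parsed FHIR R4 ConceptMap: (source_code -> target codings) per group."""

    id: str
    # (source_system, source_code) -> list of target Coding
    elements: dict[tuple[str, str], list[Coding]] = field(default_factory=dict)
    # parsed but unused for filtering; retained for round-trip fidelity
    equivalences: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def lookup(self, source_code: str) -> TranslateResult:
        """Translate ignoring the source system (codes are concept_ids, unique)."""
        for (_, code), targets in self.elements.items():
            if code == source_code:
                return list(targets)
        return UNMATCHED


def load_concept_map(file: Union[str, Path]) -> ConceptMap:
    """Parse a FHIR R4 ConceptMap JSON file.

    Raises ``ConceptMapError`` on a wrong resourceType or on a duplicated
    (group, source code) pair, naming the offending code.
    """
    with open(file, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("resourceType") != "ConceptMap":
        raise ConceptMapError(
            f"{file}: not a ConceptMap (resourceType={doc.get('resourceType')!r})"
        )
    cmap = ConceptMap(id=doc.get("id") or Path(file).stem)
    for group in doc.get("group", []):
        src_sys = group.get("source", "")
        tgt_sys = group.get("target", "")
        for element in group.get("element", []):
            code = element["code"]
            key = (src_sys, code)
            if key in cmap.elements:
                raise ConceptMapError(
                    f"ConceptMap {cmap.id!r}: duplicate source code {code!r} "
                    f"in group {src_sys!r}"
                )
            targets = []
            equivs = []
            for tgt in element.get("target", []):
                if tgt.get("equivalence") == "unmatched" or "code" not in tgt:
                    continue
                targets.append(
                    Coding(system=tgt_sys, code=tgt["code"], display=tgt.get("display"))
                )
                equivs.append(tgt.get("equivalence", "equivalent"))
            cmap.elements[key] = targets
            cmap.equivalences[key] = equivs
    return cmap


#: OMOP vocabulary_id -> canonical FHIR code-system URI.
DEFAULT_SYSTEM_REGISTRY: dict[str, str] = {
    "SNOMED": "http://snomed.info/sct",
    "RxNorm": "http://www.nlm.nih.gov/research/umls/rxnorm",
    "LOINC": "http://loinc.org",
    "CVX": "http://hl7.org/fhir/sid/cvx",
    "NDC": "http://hl7.org/fhir/sid/ndc",
    "ICD10CM": "http://hl7.org/fhir/sid/icd-10-cm",
    "ICD9CM": "http://hl7.org/fhir/sid/icd-9-cm",
    "UCUM": "http://unitsofmeasure.org",
}

#: System URI used when a vocabulary has no registered URI; downstream
#: validation reports it as an unknown-code-system informational finding.
UNKNOWN_SYSTEM = "urn:oid:unknown"


def _validate_registry(registry: Mapping[str, str]) -> None:
    uris = list(registry.values())
    if len(set(uris)) != len(uris):
        dupes = sorted({u for u in uris if uris.count(u) > 1})
        raise ValueError(f"system registry URIs must be unique; duplicated: {dupes}")


class TerminologyService:
    """Registry of local ConceptMaps plus the vocabulary->URI registry."""

    def __init__(self, registry: Optional[Mapping[str, str]] = None):
        self.registry: dict[str, str] = dict(registry or DEFAULT_SYSTEM_REGISTRY)
        _validate_registry(self.registry)
        self.maps: dict[str, ConceptMap] = {}

    # -- ConceptMap management ------------------------------------------------

    def register_map(self, cmap: ConceptMap) -> None:
        self.maps[cmap.id] = cmap

    def load_map(self, file: Union[str, Path]) -> ConceptMap:
        cmap = load_concept_map(file)
        self.register_map(cmap)
        return cmap

    def load_map_dir(self, maps_dir: Union[str, Path]) -> list[str]:
        """Load every ``*.json`` ConceptMap in a directory; returns map ids."""
        loaded = []
        for path in sorted(Path(maps_dir).glob("*.json")):
            loaded.append(self.load_map(path).id)
        return loaded

    def require_maps(self, map_ids: Iterable[str]) -> None:
        """Fail fast if any builder-referenced map is absent."""
        missing = [m for m in map_ids if m not in self.maps]
        if missing:
            raise KeyError(f"required ConceptMaps not loaded: {missing}")

    def translate(self, map_id: str, source_code: Union[str, int]) -> TranslateResult:
        """All target codings for ``source_code``, or :data:`UNMATCHED`."""
        if map_id not in self.maps:
            raise KeyError(f"unknown ConceptMap id {map_id!r}")
        return self.maps[map_id].lookup(str(source_code))

    def translate_first(self, map_id: str, source_code: Union[str, int]) -> Optional[Coding]:
        result = self.translate(map_id, source_code)
        if isinstance(result, Unmatched) or not result:
            return None
        return result[0]

    # -- vocabulary registry --------------------------------------------------

    def system_for(self, vocabulary_id: str) -> str:
        return self.registry.get(vocabulary_id, UNKNOWN_SYSTEM)

    def apply_registry_overrides(self, overrides: Mapping[str, str]) -> None:
        merged = dict(self.registry)
        merged.update(overrides)
        _validate_registry(merged)
        self.registry = merged


def concept_coding(
    concept_id,
    store,
    service: TerminologyService,
) -> TranslateResult:
    """Resolve an OMOP concept_id into a Coding via the CONCEPT table.

    ``concept_id`` 0 (the OMOP "no matching concept") or an id absent from
    CONCEPT yields :data:`UNMATCHED`.  A vocabulary with no registered URI
    yields a Coding under :data:`UNKNOWN_SYSTEM` so downstream validation can
    flag it rather than dropping the source information.
    """
    if concept_id in (None, 0, "0", ""):
        return UNMATCHED
    concept = store.get_concept(int(concept_id))
    if concept is None:
        return UNMATCHED
    return [
        Coding(
            system=service.system_for(concept["vocabulary_id"]),
            code=str(concept["concept_code"]),
            display=str(concept["concept_name"]),
        )
    ]


def default_maps_dir() -> Path:
    """Directory of the ConceptMaps shipped with the package."""
    return Path(str(_ilres.files("omopfhir") / "maps"))
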
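"""Subset FHIR / US Core conformance checking.

This is deliberately a data-driven subset validator, not a
StructureDefinition engine: required-element and binding rules live in a
YAML rule file per resource type, while three generic checks run on every
resource — period ordering (``start <= end``), coding verification against
the loaded OMOP CONCEPT table (standing in for a terminology server), and
extension-URL recognition.

Finding categories mirror the error taxonomy observed in production use of
the stock HL7 validator, with a fixed category -> severity pairing:

=====================  ========
element-cardinality    error
code-not-in-system     error
invariant-violation    error
code-not-in-valueset   warning
no-coding-from-valueset warning
label-mismatch         warning
unknown-extension      info
unknown-code-system    info
=====================  ========

The non-compliance rate counts *resources* with at least one error-level
finding over resources checked — warnings and informational findings do
not make a resource non-compliant.  Validation never mutates or drops a
resource; non-conformant resources continue through the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .terminology import TerminologyService, UNKNOWN_SYSTEM

__all__ = [
    "SEVERITY",
    "ValidationIssue",
    "ValidationReport",
    "Validator",
]

#: Fixed category -> severity pairing.
SEVERITY: dict[str, str] = {
    "element-cardinality": "error",
    "code-not-in-system": "error",
    "invariant-violation": "error",
    "code-not-in-valueset": "warning",
    "no-coding-from-valueset": "warning",
    "label-mismatch": "warning",
    "unknown-extension": "info",
    "unknown-code-system": "info",
}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    category: str
    resource_ref: str
    message: str

    def __post_init__(self) -> None:
        if SEVERITY.get(self.category) != self.severity:
            raise ValueError(
                f"category {self.category!r} must have severity {SEVERITY.get(self.category)!r}"
            )


def _issue(category: str, ref: str, message: str) -> ValidationIssue:
    return ValidationIssue(SEVERITY[category], category, ref, message)


@dataclass
class ValidationReport:
    resources_checked: int = 0
    resources_with_error: int = 0
    totals_by_category: dict[str, int] = field(default_factory=dict)
    totals_by_severity: dict[str, int] = field(default_factory=dict)
    issues: list[ValidationIssue] = field(default_factory=list)
    empty: bool = True

    @property
    def non_compliance_rate(self) -> float:
        if self.resources_checked == 0:
            return 0.0
        return self.resources_with_error / self.resources_checked

    def to_dict(self) -> dict:
        return {
            "resources_checked": self.resources_checked,
            "resources_with_error": self.resources_with_error,
            "non_compliance_rate": self.non_compliance_rate,
            "empty": self.empty,
            "totals_by_category": dict(sorted(self.totals_by_category.items())),
            "totals_by_severity": dict(sorted(self.totals_by_severity.items())),
        }

    def format_table(self) -> str:
        lines = [f"{'category':<26}{'severity':<10}{'count':>6}"]
        for cat, n in sorted(self.totals_by_category.items()):
            lines.append(f"{cat:<26}{SEVERITY[cat]:<10}{n:>6}")
        lines.append(
            f"resources checked: {self.resources_checked}; "
            f"with errors: {self.resources_with_error}; "
            f"non-compliance rate: {self.non_compliance_rate:.4f}"
        )
        return "\n".join(lines)


def _default_rules_path() -> Path:
    return Path(str(_ilres.files("omopfhir") / "config" / "validation_rules.yaml"))


def _parse_date_prefix(value: str) -> Optional[date]:
    m = re.match(r"(\d{4})-(\d{2})-(\d{2})", str(value))
    if not m:
        return None
    try:
        return date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    except ValueError:
        return None


class Validator:
    """Rule-driven conformance checker over FHIR resource JSON bodies."""

    def __init__(
        self,
        terminology: TerminologyService,
        code_index: Optional[set[tuple[str, str]]] = None,
        concept_names: Optional[dict[tuple[str, str], str]] = None,
        rules_path: Optional[Union[str, Path]] = None,
    ):
        with open(rules_path or _default_rules_path(), encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        self.rules: dict[str, dict] = doc.get("resources", {})
        self.known_extensions = set(doc.get("known_extensions", []))
        self.structural_systems = set(doc.get("structural_systems", []))
        self.terminology = terminology
        # system URI -> OMOP vocabulary, for CONCEPT-table code checks
        self._uri_to_vocab = {uri: voc for voc, uri in terminology.registry.items()}
        self.code_index = code_index            # {(vocabulary, code)}
        self.concept_names = concept_names or {}  # {(vocabulary, code): label}

    @classmethod
    def from_store(cls, terminology: TerminologyService, store,
                   rules_path: Optional[Union[str, Path]] = None) -> "Validator":
        names = {}
        for c in store._concept_index.values():
            names[(c["vocabulary_id"], str(c["concept_code"]))] = str(c["concept_name"])
        return cls(
            terminology,
            code_index=set(names),
            concept_names=names,
            rules_path=rules_path,
        )

    # -------------------------------------------------------------- checking

    def validate_resource(self, resource) -> list[ValidationIssue]:
        """All findings for one resource body (or FhirResource); pure."""
        body = resource.body if hasattr(resource, "body") else resource
        rtype = body.get("resourceType", "?")
        ref = getattr(resource, "local_ref", None) or f"{rtype}/{body.get('id', '?')}"
        issues: list[ValidationIssue] = []

        spec = self.rules.get(rtype, {})
        for element in spec.get("required", []):
            if element.endswith("[x]"):  # FHIR choice type: any variant counts
                prefix = element[:-3]
                present = any(
                    k.startswith(prefix) and v not in (None, "", [], {})
                    for k, v in body.items()
                )
            else:
                present = element in body and body[element] not in (None, "", [], {})
            if not present:
                issues.append(_issue(
                    "element-cardinality", ref,
                    f"{rtype}.{element} is a required element but is missing",
                ))
        for binding in spec.get("code_bindings", []):
            value = body.get(binding["path"])
            if value is not None and value not in binding["allowed"]:
                issues.append(_issue(
                    "code-not-in-valueset", ref,
                    f"{rtype}.{binding['path']} value {value!r} not in bound value set",
                ))
        for req in spec.get("require_coding_from", []):
            cc = body.get(req["path"])
            if isinstance(cc, dict):
                systems = {c.get("system") for c in cc.get("coding", [])}
                if req["system"] not in systems:
                    issues.append(_issue(
                        "no-coding-from-valueset", ref,
                        f"{rtype}.{req['path']} has no coding from {req['system']}",
                    ))

        self._walk(body, rtype, ref, issues)
        return issues

    def _walk(self, node, rtype: str, ref: str, issues: list[ValidationIssue],
              path: str = "") -> None:
        if isinstance(node, dict):
            if "start" in node and "end" in node:
                self._check_period(node, rtype, ref, issues, path)
            if "system" in node and "code" in node and "resourceType" not in node:
                self._check_coding(node, ref, issues, path)
            for url_entry in node.get("extension", []) if isinstance(
                node.get("extension"), list) else []:
                url = url_entry.get("url", "")
                if url and url not in self.known_extensions and "/" not in path:
                    # only top-level unknown extensions are reported once
                    issues.append(_issue(
                        "unknown-extension", ref, f"unknown extension url {url!r}"
                    ))
            for key, value in node.items():
                if key == "extension":
                    # nested component urls (ombCategory/text) are positional,
                    # not canonical extension identifiers
                    for sub in value if isinstance(value, list) else []:
                        for k2, v2 in sub.items() if isinstance(sub, dict) else []:
                            if k2 != "url":
                                self._walk(v2, rtype, ref, issues, f"{path}/{key}")
                    continue
                self._walk(value, rtype, ref, issues, f"{path}/{key}")
        elif isinstance(node, list):
            for item in node:
                self._walk(item, rtype, ref, issues, path)

    def _check_period(self, node: dict, rtype: str, ref: str,
                      issues: list[ValidationIssue], path: str) -> None:
        start = _parse_date_prefix(node.get("start") or "")
        end = _parse_date_prefix(node.get("end") or "")
        if start and end and start > end:
            issues.append(_issue(
                "invariant-violation", ref,
                f"{rtype}{path}: period start {node['start']} is later than end {node['end']}",
            ))

    def _check_coding(self, coding: dict, ref: str,
                      issues: list[ValidationIssue], path: str) -> None:
        system = coding.get("system", "")
        code = str(coding.get("code", ""))
        if system in self.structural_systems:
            return
        vocab = self._uri_to_vocab.get(system)
        if vocab is None or system == UNKNOWN_SYSTEM:
            issues.append(_issue(
                "unknown-code-system", ref,
                f"{path}: code system {system!r} is not known to the terminology source",
            ))
            return
        if self.code_index is None:
            return
        if (vocab, code) not in self.code_index:
            issues.append(_issue(
                "code-not-in-system", ref,
                f"{path}: code {code!r} not found in code system {vocab}",
            ))
            return
        display = coding.get("display")
        expected = self.concept_names.get((vocab, code))
        if display is not None and expected is not None:
            if _normalize_label(display) != _normalize_label(expected):
                issues.append(_issue(
                    "label-mismatch", ref,
                    f"{path}: display {display!r} does not match label {expected!r}",
                ))

    # ----------------------------------------------------------- aggregation

    @staticmethod
    def summarize(reports: Iterable[list[ValidationIssue]]) -> ValidationReport:
        """Aggregate per-resource issue lists; rate is over resources."""
        out = ValidationReport()
        for issues in reports:
            out.empty = False
            out.resources_checked += 1
            if any(i.severity == "error" for i in issues):
                out.resources_with_error += 1
            for issue in issues:
                out.issues.append(issue)
                out.totals_by_category[issue.category] = (
                    out.totals_by_category.get(issue.category, 0) + 1
                )
                out.totals_by_severity[issue.severity] = (
                    out.totals_by_severity.get(issue.severity, 0) + 1
                )
        return out


def _normalize_label(label: str) -> str:
    """Whitespace-normalized, truncated at 256 chars (source-label limit)."""
    return re.sub(r"\s+", " ", label.strip())[:256]
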
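"""Smoking-survey concatenation, parsing, and the six-code status collapse.

OMOP stores each answer of a smoking questionnaire as its own OBSERVATION
row (up to 10 rows per survey).  Because one FHIR resource must be built
from one row, all answers given within an encounter are concatenated into a
single source-value string of the form::

    (Chew:No) – (Cigarettes:No) – (TobaccoUse:Yes)

components sorted by question name, joined by " – " (en dash).  A component
without a colon is a free-text answerless entry (e.g. a dependence
diagnosis recorded alongside the survey) and renders as ``(text)``.

The concatenated string is then collapsed onto one of the six SNOMED codes
the US Core smoking-status profile allows, via an ordered first-match rule
table (:class:`SmokingRules`); the full string is always retained as the
CodeableConcept.text so the raw survey selections survive the collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .terminology import Coding, TerminologyService, Unmatched

__all__ = [
    "SmokingResponse",
    "render_smoking_source_value",
    "parse_smoking_source_value",
    "SmokingRules",
    "SEPARATOR",
]

#: Verbatim separator between rendered components (space, en dash, space).
SEPARATOR = " – "

#: Question names of the smoking survey; OBSERVATION rows whose
#: observation_source_value starts with one of these (before the colon) are
#: aggregated into a single smoking Observation per encounter.
SMOKING_QUESTIONS = (
    "Chew",
    "CigarettePacksPerDay",
    "Cigarettes",
    "Cigars",
    "Pipes",
    "Snuff",
    "TobaccoUse",
    "TobaccoUseInYears",
)


@dataclass(frozen=True, order=True)
class SmokingResponse:
    """One survey component; ``answer`` is None for free-text entries."""

    question: str
    answer: Optional[str] = None

    def render(self) -> str:
        if self.answer is None:
            return f"({self.question})"
        return f"({self.question}:{self.answer})"


def render_smoking_source_value(responses: Sequence[SmokingResponse]) -> str:
    """Concatenate responses, sorted by question name, into one string."""
    ordered = sorted(responses, key=lambda r: (r.question, r.answer or ""))
    return SEPARATOR.join(r.render() for r in ordered)


def parse_smoking_source_value(value: str) -> list[SmokingResponse]:
    """Exact inverse of :func:`render_smoking_source_value`.

    An empty string yields an empty list.  Raises ``ValueError`` on a
    component not wrapped in parentheses.
    """
    if not value:
        return []
    out = []
    for part in value.split(SEPARATOR):
        if not (part.startswith("(") and part.endswith(")")):
            raise ValueError(f"malformed smoking component: {part!r}")
        body = part[1:-1]
        if ":" in body:
            q, a = body.split(":", 1)
            out.append(SmokingResponse(question=q, answer=a))
        else:
            out.append(SmokingResponse(question=body, answer=None))
    return out


class SmokingRules:
    """Ordered first-match rules collapsing survey answers onto 6 codes."""

    def __init__(self, rules: list[dict], default_category: str):
        self.rules = rules
        self.default_category = default_category

    @classmethod
    def load(cls, path: Optional[Union[str, Path]] = None) -> "SmokingRules":
        if path is None:
            path = Path(str(_ilres.files("omopfhir") / "config" / "smoking_rules.yaml"))
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(rules=doc["rules"], default_category=doc["default_category"])

    def category_for(self, responses: Sequence[SmokingResponse]) -> str:
        """Category of the first rule whose (question, answer) pairs all match."""
        answers = {r.question: r.answer for r in responses if r.answer is not None}
        for rule in self.rules:
            if all(answers.get(q) == a for q, a in rule["when"].items()):
                return rule["category"]
        return self.default_category

    def map_code(
        self, responses: Sequence[SmokingResponse], service: TerminologyService
    ) -> Coding:
        """Map responses to one of the six allowed SNOMED smoking codes.

        Total function: falls back to the configured unknown-if-ever-smoked
        category when no rule fires.  The allowed-code set size is asserted
        at first use.
        """
        allowed = allowed_smoking_codes(service)
        if len(allowed) != 6:
            raise ValueError(
                f"smoking-status ConceptMap must define exactly 6 codes, got {len(allowed)}"
            )
        category = self.category_for(responses)
        coding = service.translate_first("smoking-status", category)
        if coding is None:  # category outside the map would be a config bug
            raise KeyError(f"smoking category {category!r} not in smoking-status map")
        return coding


def allowed_smoking_codes(service: TerminologyService) -> set[str]:
    """The SNOMED codes reachable through the smoking-status ConceptMap."""
    cmap = service.maps.get("smoking-status")
    if cmap is None:
        raise KeyError("smoking-status ConceptMap not loaded")
    codes = set()
    for targets in cmap.elements.values():
        if not isinstance(targets, Unmatched):
            codes.update(t.code for t in targets)
    return codes
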
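"""Structured-field extraction from free-text preoperative notes.

Four target aspects are extracted from the "case characteristics and
preoperative preparation" narrative: prepuce, testicular, scrotal and penile
characteristics. Each extracted value must carry an evidence span that is a
verbatim substring of the source note; extraction consistency is scored with
a hallucination-zero rule (any fabricated field zeroes the case, omissions
score proportionally).

Backends are pluggable: a deterministic rule backend (needs nothing
external; the tested path) and a remote LLM backend driven by a prompt
template (never exercised offline).
"""

from __future__ import annotations

import json
import logging
import re
import urllib.request
from dataclasses import dataclass, field

import pandas as pd

from .catalog import NARRATIVE_FIELDS, NARRATIVE_SENTENCES

logger = logging.getLogger(__name__)

__all__ = [
    "FieldValue",
    "StructuredFields",
    "RuleBackend",
    "LLMBackend",
    "RetriableBackendError",
    "extract_fields",
    "score_extraction",
    "score_cohort",
    "PROMPT_TEMPLATE",
]


AGE_IN_NOTE_RE = re.compile(r"aged\s+(\d+)\s+years?\s+(\d+)\s+months?", re.IGNORECASE)


@dataclass(frozen=True)
class FieldValue:
    """One extracted aspect: structured value plus its verbatim evidence."""

    value: str
    evidence: str

    def __post_init__(self):
        if self.value and not self.evidence:
            raise ValueError("a non-missing extracted value requires a non-empty evidence span")


@dataclass
class StructuredFields:
    """The 4 structured narrative aspects of one note (missing -> None)."""

    fields: dict[str, FieldValue | None] = field(
        default_factory=lambda: {f: None for f in NARRATIVE_FIELDS}
    )
    extracted_age: float | None = None

    def __getitem__(self, name: str) -> FieldValue | None:
        return self.fields[name]

    def present(self) -> dict[str, FieldValue]:
        return {k: v for k, v in self.fields.items() if v is not None}

    def to_dict(self) -> dict:
        return {
            "fields": {
                k: (None if v is None else {"value": v.value, "evidence": v.evidence})
                for k, v in self.fields.items()
            },
            "extracted_age": self.extracted_age,
        }


class RetriableBackendError(RuntimeError):
    """Transport-level backend failure; the call may be retried."""


class RuleBackend:
    """Deterministic extraction by matching the known sentence catalog.

    The synthetic narrative renderer and this backend share the attribute
    sentence table, so on noise-free synthetic notes extraction is exact.
    """

    def __init__(self, sentences: dict[str, dict[str, str]] | None = None):
        self.sentences = sentences if sentences is not None else NARRATIVE_SENTENCES

    def extract(self, note: str | None) -> StructuredFields:
        out = StructuredFields()
        if not note:
            return out
        for fld, attrs in self.sentences.items():
            for template in attrs.values():
                candidates = (
                    [template.format(side=s) for s in ("left", "right")]
                    if "{side}" in template
                    else [template]
                )
                hit = next((c for c in candidates if c in note), None)
                if hit is not None:
                    out.fields[fld] = FieldValue(value=hit, evidence=hit)
                    break
        m = AGE_IN_NOTE_RE.search(note)
        if m:
            out.extracted_age = int(m.group(1)) + int(m.group(2)) / 12.0
        return out


PROMPT_TEMPLATE = """\
You are a clinical information extraction assistant. From the pediatric
urology preoperative note below, extract the following structured fields:
  1. prepuce characteristics description
  2. testicular characteristics description
  3. scrotal characteristics description
  4. penile characteristics description
For every field you populate, also return the exact original text segment
(verbatim substring of the note) supporting it, so the output can be checked
against the source. If an aspect is not described, return null for it. Never
infer or invent information that is not stated in the note. Also extract the
patient's age in years if it is mentioned.

Return strictly this JSON shape:
{"prepuce": {"value": ..., "evidence": ...} | null,
 "testicular": {"value": ..., "evidence": ...} | null,
 "scrotal": {"value": ..., "evidence": ...} | null,
 "penile": {"value": ..., "evidence": ...} | null,
 "age_years": number | null}

Note:
{note}
"""


class LLMBackend:
    """Prompted remote extraction over an HTTP JSON API.

    Configured from the run config (endpoint, model, credentials reference);
    malformed fields in the response are dropped with a warning, never
    fabricated. Not used in the offline pipeline.
    """

    def __init__(self, endpoint: str, model: str = "", api_key: str = "",
                 prompt_template: str = PROMPT_TEMPLATE, timeout: float = 30.0):
        self.endpoint = endpoint
        self.model = model
        self.api_key = api_key
        self.prompt_template = prompt_template
        self.timeout = timeout

    def extract(self, note: str | None) -> StructuredFields:
        if not note:
            return StructuredFields()
        payload = json.dumps(
            {"model": self.model, "prompt": self.prompt_template.replace("{note}", note)}
        ).encode()
        req = urllib.request.Request(
            self.endpoint, data=payload,
            headers={"Content-Type": "application/json",
                     "Authorization": f"Bearer {self.api_key}"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode())
        except (OSError, ValueError) as exc:
            raise RetriableBackendError(f"extraction backend transport failure: {exc}") from exc
        out = StructuredFields()
        for fld in NARRATIVE_FIELDS:
            item = body.get(fld)
            if item is None:
                continue
            try:
                out.fields[fld] = FieldValue(value=str(item["value"]),
                                             evidence=str(item["evidence"]))
            except (KeyError, TypeError, ValueError):
                logger.warning("malformed backend output for field %r dropped", fld)
        age = body.get("age_years")
        if isinstance(age, (int, float)):
            out.extracted_age = float(age)
        return out


def extract_fields(note: str | None, backend) -> StructuredFields:
    """Extract the 4 structured aspects (plus age) from one note."""
    return backend.extract(note)


def score_extraction(
    extracted: StructuredFields,
    source: str | None,
    truth: dict[str, str],
    per_field: bool = False,
) -> float:
    """Consistency score in [0, 100] for one case.

    A populated field is *fabricated* when its evidence span is not a
    verbatim substring of the source note, when its value contradicts the
    reference, or when the reference has no such aspect at all. Under the
    default per-case rule any fabrication scores the whole case 0; otherwise
    the score is 100 x (correctly extracted aspects) / (reference aspects).
    ``per_field=True`` instead zeroes only the fabricated fields and averages
    over the union of reference and populated fields.
    """
    source = source or ""
    statuses = _field_statuses(extracted, source, truth)
    relevant = [f for f, s in statuses.items() if s != "absent"]
    if not relevant:
        return 100.0
    if per_field:
        return 100.0 * sum(statuses[f] == "correct" for f in relevant) / len(relevant)
    if any(statuses[f] == "fabricated" for f in relevant):
        return 0.0
    n_truth = sum(1 for f in relevant if f in truth)
    if n_truth == 0:
        return 100.0
    return 100.0 * sum(statuses[f] == "correct" for f in relevant) / n_truth


def _field_statuses(
    extracted: StructuredFields, source: str, truth: dict[str, str]
) -> dict[str, str]:
    statuses: dict[str, str] = {}
    for fld in NARRATIVE_FIELDS:
        val = extracted.fields.get(fld)
        if val is None:
            statuses[fld] = "omitted" if fld in truth else "absent"
        elif val.evidence not in source:
            statuses[fld] = "fabricated"
        elif fld not in truth or val.value != truth[fld]:
            statuses[fld] = "fabricated"
        else:
            statuses[fld] = "correct"
    return statuses


def score_cohort(
    items: list[tuple[str, StructuredFields, str | None, dict[str, str]]],
    per_field: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Score many cases; returns (mean score, per-case/field report).

    ``items`` rows are (case_id, extracted, source note, truth fields).
    """
    rows = []
    scores = []
    for case_id, extracted, source, truth in items:
        s = score_extraction(extracted, source, truth, per_field=per_field)
        scores.append(s)
        for fld, status in _field_statuses(extracted, source or "", truth).items():
            if status != "absent":
                rows.append({"case_id": case_id, "field": fld, "status": status, "score": s})
    mean = float(sum(scores) / len(scores)) if scores else 100.0
    return mean, pd.DataFrame(rows, columns=["case_id", "field", "status", "score"])
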
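"""Discharge-summary parsing: section segmentation, presenting-complaint
passage isolation, and medication-table region detection.

All offsets are 0-based, half-open character indices into the original
document string, so concatenating the section passages in order reconstructs
the document byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .lexicon import normalize_term

__all__ = [
    "DEFAULT_HEADING_PATTERNS",
    "PRESENTING_HEADING_PATTERNS",
    "TRIGGER_PHRASES",
    "MEDICATION_INDICATOR_TERMS",
    "DischargeSummary",
    "Passage",
    "TableRegion",
    "segment_sections",
    "extract_presenting_passage",
    "detect_medication_tables",
    "read_corpus",
    "write_corpus",
]

#: Section headings recognized at line starts (case-insensitive).  These are a
#: reconstruction of common summary layouts and are fully overridable.
DEFAULT_HEADING_PATTERNS: tuple[str, ...] = (
    r"presenting complaints?\s*:",
    r"chief complaints?\s*:",
    r"history of presenting illness\s*:",
    r"history of present illness\s*:",
    r"presenting history\s*:",
    r"history\s*:",
    r"examination\s*:",
    r"physical exam(?:ination)?\s*:",
    r"investigations?\s*:",
    r"hospital course\s*:",
    r"course in hospital\s*:",
    r"procedures?\s*:",
    r"diagnosis\s*:",
    r"discharge medications?\s*:",
    r"medications? on discharge\s*:",
    r"condition at discharge\s*:",
    r"follow ?up\s*:",
    r"plan\s*:",
)

#: A section whose heading matches one of these regexes is treated as the
#: presenting-complaint passage.
PRESENTING_HEADING_PATTERNS: tuple[str, ...] = (
    r"presenting complaints?",
    r"chief complaints?",
    r"history of present(?:ing)? illness",
    r"presenting history",
)

#: Fallback phrases that identify a presenting-complaint passage in free text.
TRIGGER_PHRASES: tuple[str, ...] = (
    "presented with",
    "presenting with",
    "complaints of",
    "complained of",
    "complaining of",
)

MEDICATION_INDICATOR_TERMS: tuple[str, ...] = (
    "discharge medications",
    "medications on discharge",
    "discharge medication",
)

GENDERS = ("woman", "man")


class CorpusError(ValueError):
    """Raised for invalid summaries or corpus files."""


@dataclass(frozen=True)
class DischargeSummary:
    """One discharge summary plus its admission metadata."""

    doc_id: str
    text: str
    gender: str
    age_years: float
    admission_year: int
    diabetes: bool
    pci: bool

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if self.gender not in GENDERS:
            raise CorpusError(f"{self.doc_id}: gender must be one of {GENDERS}")
        if self.age_years < 0:
            raise CorpusError(f"{self.doc_id}: age_years must be non-negative")

    def validate_year(self, year_range: tuple[int, int] = (1988, 2018)) -> None:
        lo, hi = year_range
        if not lo <= self.admission_year <= hi:
            raise CorpusError(
                f"{self.doc_id}: admission_year {self.admission_year} outside "
                f"[{lo}, {hi}]"
            )

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "text": self.text,
            "gender": self.gender,
            "age_years": self.age_years,
            "admission_year": self.admission_year,
            "diabetes": self.diabetes,
            "pci": self.pci,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "DischargeSummary":
        return cls(
            doc_id=str(obj["doc_id"]),
            text=str(obj["text"]),
            gender=str(obj["gender"]),
            age_years=float(obj["age_years"]),
            admission_year=int(obj["admission_year"]),
            diabetes=bool(obj["diabetes"]),
            pci=bool(obj["pci"]),
        )


@dataclass(frozen=True)
class Passage:
    text: str
    section_label: str
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_offset < self.end_offset:
            raise CorpusError("passage offsets must satisfy 0 <= start < end")


@dataclass(frozen=True)
class TableRegion:
    rows: tuple[str, ...]
    start_offset: int
    end_offset: int
    indicator_term: str


def _compile(patterns: Sequence[str]) -> list[re.Pattern]:
    try:
        return [re.compile(p, re.IGNORECASE) for p in patterns]
    except re.error as exc:
        raise CorpusError(f"invalid heading regex: {exc}") from exc


def segment_sections(
    text: str, heading_patterns: Sequence[str] = DEFAULT_HEADING_PATTERNS
) -> list[Passage]:
    """Split a document into labeled, non-overlapping passages at heading lines.

    A heading opens a new passage at the start of its line; text before the
    first heading becomes a ``preamble`` passage.  Concatenating the returned
    passage texts reproduces the input exactly.
    """
    if not text:
        return []
    compiled = _compile(heading_patterns)

    boundaries: dict[int, str] = {}  # line start offset -> section label
    pos = 0
    for line in text.splitlines(keepends=True):
        stripped = line.lstrip()
        for pat in compiled:
            m = pat.match(stripped)
            if m:
                label = normalize_term(m.group(0).rstrip(":"))
                boundaries.setdefault(pos, label)
                break
        pos += len(line)

    starts = sorted(boundaries)
    passages: list[Passage] = []
    if not starts or starts[0] > 0:
        end = starts[0] if starts else len(text)
        passages.append(Passage(text[:end], "preamble", 0, end))
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else len(text)
        passages.append(Passage(text[start:end], boundaries[start], start, end))
    return passages


def extract_presenting_passage(
    doc: DischargeSummary,
    heading_patterns: Sequence[str] = DEFAULT_HEADING_PATTERNS,
    trigger_phrases: Sequence[str] = TRIGGER_PHRASES,
    presenting_patterns: Sequence[str] = PRESENTING_HEADING_PATTERNS,
) -> Optional[Passage]:
    """Locate the presenting-complaint passage, or return None.

    Preference order: earliest section whose heading matches a
    presenting-complaint pattern, then the earliest passage (including the
    preamble) containing a trigger phrase.  ``None`` is the valid
    "no passage found" outcome used in flow accounting.
    """
    passages = segment_sections(doc.text, heading_patterns)
    compiled = _compile(presenting_patterns)
    for passage in passages:
        if passage.section_label == "preamble":
            continue
        if any(p.fullmatch(passage.section_label) for p in compiled):
            return passage
    triggers = [normalize_term(t) for t in trigger_phrases]
    for passage in passages:
        normalized = normalize_term(passage.text)
        if any(t in normalized for t in triggers):
            return passage
    return None


_HEADING_LINE = re.compile(r"^\s*[A-Za-z][A-Za-z0-9 /&'()-]{0,60}:\s*$")


def detect_medication_tables(
    text: str, indicator_terms: Sequence[str] = MEDICATION_INDICATOR_TERMS
) -> list[TableRegion]:
    """Find medication-table regions triggered by indicator headings.

    Each region runs from the line after the indicator to the next
    heading-looking line (or end of document) and is split into non-empty row
    strings.  Regions are returned in offset order; an empty list means no
    indicator was found.
    """
    indicators = [normalize_term(t) for t in indicator_terms if normalize_term(t)]
    if not indicators or not text:
        return []

    lines: list[tuple[int, str]] = []  # (start offset, line without newline)
    pos = 0
    for raw in text.splitlines(keepends=True):
        lines.append((pos, raw.rstrip("\n")))
        pos += len(raw)

    regions: list[TableRegion] = []
    i = 0
    while i < len(lines):
        offset, line = lines[i]
        norm = normalize_term(line)
        hit = next((t for t in indicators if t in norm), None)
        if hit is None:
            i += 1
            continue
        rows: list[str] = []
        start = None
        end = offset + len(line)
        j = i + 1
        while j < len(lines):
            row_offset, row_line = lines[j]
            row_norm = normalize_term(row_line)
            if _HEADING_LINE.match(row_line) or any(t in row_norm for t in indicators):
                break
            if row_line.strip():
                if start is None:
                    start = row_offset
                rows.append(row_line.strip())
                end = row_offset + len(row_line)
            j += 1
        if rows:
            regions.append(
                TableRegion(tuple(rows), start if start is not None else end, end, hit)
            )
        i = j
    return regions


def read_corpus(path: Union[str, Path]) -> list[DischargeSummary]:
    """Read a JSON-lines corpus, one summary object per line."""
    docs: list[DischargeSummary] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc.msg}") from exc
            doc = DischargeSummary.from_dict(obj)
            if doc.doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_corpus(docs: Iterable[DischargeSummary], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_dict()) + "\n")
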
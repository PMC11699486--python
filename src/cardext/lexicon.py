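"""Symptom lexicon and medication dictionary: types, normalization, loaders.

The extractors never see raw user text or raw dictionary rows; everything is
funneled through :func:`normalize_term` so matching is case-, punctuation- and
whitespace-insensitive by construction.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "DRUG_CLASSES",
    "UNKNOWN",
    "BUILTIN",
    "SymptomConcept",
    "MedicationEntry",
    "NegationConfig",
    "normalize_term",
    "load_symptom_lexicon",
    "save_symptom_lexicon",
    "load_medication_dictionary",
    "save_medication_dictionary",
]

#: Closed set of modeled drug classes; everything else is UNKNOWN.
DRUG_CLASSES: tuple[str, ...] = (
    "aspirin",
    "statin",
    "clopidogrel",
    "beta_blocker",
    "antidiabetic",
    "ace_inhibitor",
    "arb",
    "aspirin_clopidogrel_combo",
    "ticagrelor",
)

UNKNOWN = "UNKNOWN"

#: Marker accepted by the loaders to request the packaged default resources.
BUILTIN = "builtin"

_DATA_DIR = Path(__file__).parent / "data"


class LexiconError(ValueError):
    """Raised for malformed or invalid lexicon/dictionary inputs."""


def normalize_term(raw: str) -> str:
    """Lowercase, fold to ASCII where possible, map punctuation to spaces and
    collapse whitespace runs.  Idempotent; empty input yields empty output."""
    if not raw:
        return ""
    out = []
    for ch in unicodedata.normalize("NFKD", raw):
        if unicodedata.combining(ch):
            continue  # accent marks fold away, they must not split words
        out.append(ch if ch.isalnum() else " ")
    text = "".join(out).encode("ascii", "ignore").decode("ascii").lower()
    return " ".join(text.split())


@dataclass(frozen=True)
class SymptomConcept:
    """A canonical symptom with the synonym phrases that count as mentions."""

    canonical_name: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise LexiconError("canonical_name must be non-empty")
        if not self.synonyms:
            raise LexiconError(f"concept {self.canonical_name!r} has no synonyms")
        for syn in self.synonyms:
            if not syn or syn != syn.strip() or syn != syn.lower():
                raise LexiconError(
                    f"synonym {syn!r} of {self.canonical_name!r} is not a "
                    "non-empty, stripped, lowercase phrase"
                )

    @property
    def multiword(self) -> bool:
        return max(len(s.split()) for s in self.synonyms) > 1


@dataclass(frozen=True)
class MedicationEntry:
    """One normalized medication name mapped to a drug class."""

    name: str
    drug_class: str
    source: str = "dictionary"  # dictionary | regex_derived | manual

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconError("medication name must be non-empty")
        if self.drug_class not in DRUG_CLASSES and self.drug_class != UNKNOWN:
            raise LexiconError(
                f"unknown drug class {self.drug_class!r}; permitted classes: "
                f"{', '.join(DRUG_CLASSES)} or {UNKNOWN}"
            )
        if self.source not in ("dictionary", "regex_derived", "manual"):
            raise LexiconError(f"invalid source {self.source!r}")


@dataclass(frozen=True)
class NegationConfig:
    """Cue vocabulary and proximity window for negation detection.

    The cue set extends the obvious two-word core (no/not) with common clinical
    deniers; it is fully overridable.
    """

    cue_terms: frozenset[str] = frozenset(
        {"no", "not", "denies", "denied", "without", "nil"}
    )
    window_tokens: int = 3
    sentence_bounded: bool = True

    def __post_init__(self) -> None:
        if self.window_tokens < 1:
            raise LexiconError("window_tokens must be >= 1")
        if not self.cue_terms:
            raise LexiconError("cue set must be non-empty")
        object.__setattr__(self, "cue_terms", frozenset(self.cue_terms))


def load_symptom_lexicon(source: Union[str, Path] = BUILTIN) -> list[SymptomConcept]:
    """Load a symptom lexicon from a JSON file or the packaged default.

    File format: a JSON array of ``{"canonical": str, "synonyms": [str]}``
    objects.  All synonyms are normalized on load; the normalized canonical
    name is always included as a synonym.
    """
    path = _DATA_DIR / "symptom_lexicon.json" if source == BUILTIN else Path(source)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LexiconError(f"malformed lexicon file {path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, list):
        raise LexiconError(f"lexicon file {path} must contain a JSON array")

    concepts: list[SymptomConcept] = []
    seen: set[str] = set()
    for obj in payload:
        canonical = normalize_term(str(obj["canonical"]))
        if canonical in seen:
            raise LexiconError(f"duplicate canonical name {canonical!r}")
        seen.add(canonical)
        synonyms = [normalize_term(s) for s in obj.get("synonyms", [])]
        synonyms = [s for s in synonyms if s]
        if canonical not in synonyms:
            synonyms.insert(0, canonical)
        # stable de-dup, preserving order
        synonyms = list(dict.fromkeys(synonyms))
        concepts.append(SymptomConcept(canonical, tuple(synonyms)))
    return concepts


def save_symptom_lexicon(concepts: Iterable[SymptomConcept], path: Union[str, Path]) -> None:
    payload = [
        {"canonical": c.canonical_name, "synonyms": list(c.synonyms)} for c in concepts
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_medication_dictionary(
    source: Union[str, Path] = BUILTIN,
) -> dict[str, MedicationEntry]:
    """Load a name -> MedicationEntry mapping from a ``name,class`` CSV."""
    path = _DATA_DIR / "medication_dictionary.csv" if source == BUILTIN else Path(source)
    entries: dict[str, MedicationEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return entries
        if "name" not in reader.fieldnames or "class" not in reader.fieldnames:
            raise LexiconError(f"{path}: expected CSV header 'name,class'")
        for lineno, row in enumerate(reader, start=2):
            name = normalize_term(row["name"])
            if not name:
                raise LexiconError(f"{path}:{lineno}: empty medication name")
            if name in entries:
                raise LexiconError(f"{path}:{lineno}: duplicate name {name!r}")
            entries[name] = MedicationEntry(name=name, drug_class=row["class"].strip())
    return entries


def save_medication_dictionary(
    entries: dict[str, MedicationEntry], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "class"])
        for name in sorted(entries):
            writer.writerow([name, entries[name].drug_class])
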
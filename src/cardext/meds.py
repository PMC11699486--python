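"""Discharge-medication extraction: row parsing, base-term normalization,
drug-class lookup with a strict fuzzy fallback, and an unknown-term queue."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .docparse import DischargeSummary, detect_medication_tables
from .lexicon import DRUG_CLASSES, UNKNOWN, MedicationEntry, normalize_term
from .symptoms import similarity

__all__ = [
    "MedicationExtraction",
    "extract_base_term",
    "classify_medication",
    "extract_patient_medications",
    "extract_corpus_medications",
]

log = logging.getLogger(__name__)

#: Leading dosage-form tokens stripped from rows.
FORM_TOKENS = frozenset({"tab", "tabs", "tablet", "cap", "caps", "capsule", "inj", "injection", "syp", "syrup", "susp", "suspension", "sachet"})

#: Trailing dose / route / frequency tokens stripped from rows.
DOSE_ROUTE_FREQ = frozenset({
    "od", "bd", "tds", "qid", "prn", "sos", "hs", "stat", "daily", "nocte",
    "sc", "po", "iv", "im", "sl",
    "mg", "g", "gm", "ml", "mcg", "ug", "iu", "unit", "units",
})

_DOSE_TOKEN = re.compile(r"^\d+(?:\.\d+)?(?:mg|g|gm|ml|mcg|ug|iu|units?)?$")


@dataclass(frozen=True)
class MedicationExtraction:
    doc_id: str
    rows_seen: int
    classified: frozenset[str]
    unknown_terms: tuple[str, ...]
    meds_found: bool

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "rows_seen": self.rows_seen,
            "classified": sorted(self.classified),
            "unknown_terms": list(self.unknown_terms),
            "meds_found": self.meds_found,
        }


def extract_base_term(row: str) -> str:
    """Reduce a medication row to its base name.

    Strips leading dosage-form tokens and trailing dose/route/frequency
    tokens from the normalized row, then keeps at most the first three
    remaining tokens.  Returns '' when nothing survives.
    """
    tokens = normalize_term(row).split()
    while tokens and tokens[0] in FORM_TOKENS:
        tokens = tokens[1:]
    while tokens and (tokens[-1] in DOSE_ROUTE_FREQ or _DOSE_TOKEN.match(tokens[-1])):
        tokens = tokens[:-1]
    # drop any interior dose-like tokens left between name and stripped tail
    cut = len(tokens)
    for i, tok in enumerate(tokens):
        if _DOSE_TOKEN.match(tok) or tok in DOSE_ROUTE_FREQ:
            cut = i
            break
    tokens = tokens[:cut]
    return " ".join(tokens[:3])


def classify_medication(
    base_term: str,
    dictionary: Mapping[str, MedicationEntry],
    fuzzy_threshold: float = 90.0,
) -> str:
    """Map a base term to a drug class.

    Exact dictionary lookup first; otherwise the best fuzzy hit over
    dictionary names at or above ``fuzzy_threshold`` wins (score ties broken
    lexicographically by name, so classification is deterministic); otherwise
    UNKNOWN.
    """
    if not base_term:
        return UNKNOWN
    entry = dictionary.get(base_term)
    if entry is not None:
        return entry.drug_class
    best_name: Optional[str] = None
    best_score = fuzzy_threshold
    max_gap = 1.0 - fuzzy_threshold / 100.0
    for name in sorted(dictionary):
        longest = max(len(name), len(base_term))
        if longest == 0 or abs(len(name) - len(base_term)) > max_gap * longest:
            continue
        score = similarity(base_term, name)
        if score > best_score or (score == best_score and best_name is None):
            best_name, best_score = name, score
    if best_name is None:
        return UNKNOWN
    log.debug("fuzzy medication lookup: %r -> %r (%.1f)", base_term, best_name, best_score)
    return dictionary[best_name].drug_class


def extract_patient_medications(
    doc: DischargeSummary,
    dictionary: Mapping[str, MedicationEntry],
    fuzzy_threshold: float = 90.0,
) -> MedicationExtraction:
    """Full per-document model: table detection, base-term extraction, lookup.

    ``meds_found`` is true iff at least one table region yielded at least one
    classified row.  Unclassified base terms are queued (deduplicated, in
    first-seen order) for manual labeling.
    """
    regions = detect_medication_tables(doc.text)
    classified: set[str] = set()
    unknown: dict[str, None] = {}
    rows_seen = 0
    for region in regions:
        for row in region.rows:
            rows_seen += 1
            term = extract_base_term(row)
            drug_class = classify_medication(term, dictionary, fuzzy_threshold)
            if drug_class == UNKNOWN:
                if term:
                    unknown.setdefault(term)
            else:
                classified.add(drug_class)
    return MedicationExtraction(
        doc_id=doc.doc_id,
        rows_seen=rows_seen,
        classified=frozenset(classified),
        unknown_terms=tuple(unknown),
        meds_found=bool(classified),
    )


def extract_corpus_medications(
    docs: Iterable[DischargeSummary],
    dictionary: Mapping[str, MedicationEntry],
    fuzzy_threshold: float = 90.0,
) -> dict[str, MedicationExtraction]:
    return {
        doc.doc_id: extract_patient_medications(doc, dictionary, fuzzy_threshold)
        for doc in docs
    }
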
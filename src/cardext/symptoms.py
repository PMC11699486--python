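"""Presenting-symptom extraction: fuzzy phrase matching with negation handling.

The similarity scale is fixed to the character-level normalized Levenshtein
formula ``100 * (1 - LEV(a, b) / max(|a|, |b|))`` and the default decision
rule is inclusive at the 80-point threshold, so a phrase at exactly 80 counts
as a match.  Matching slides an exact-k token window over the passage for each
k-token synonym; negation is a preceding-window cue search bounded at sentence
breaks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Union

from .docparse import DischargeSummary, Passage, extract_presenting_passage
from .lexicon import NegationConfig, SymptomConcept, normalize_term

__all__ = [
    "SymptomMatch",
    "ExtractionResult",
    "similarity",
    "levenshtein",
    "tokenize",
    "match_symptoms",
    "detect_negation",
    "extract_patient_symptoms",
    "extract_corpus_symptoms",
]

log = logging.getLogger(__name__)

#: Tokens that end a sentence for the purposes of negation scoping.
BOUNDARY_TOKENS = frozenset({".", ";", "\n"})

_TOKEN_RE = re.compile(r"[.;\n]|[^\s.;]+")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost character edit distance (iterative two-row DP)."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if la > lb:
        a, b, la, lb = b, a, lb, la
    prev = list(range(la + 1))
    cur = [0] * (la + 1)
    for j in range(1, lb + 1):
        cur[0] = j
        bj = b[j - 1]
        for i in range(1, la + 1):
            cur[i] = min(
                prev[i] + 1,
                cur[i - 1] + 1,
                prev[i - 1] + (a[i - 1] != bj),
            )
        prev, cur = cur, prev
    return prev[la]


@lru_cache(maxsize=1 << 18)
def _similarity_cached(a: str, b: str) -> float:
    m = max(len(a), len(b))
    if m == 0:
        return 100.0
    return 100.0 * (1.0 - levenshtein(a, b) / m)


def similarity(a: str, b: str) -> float:
    """Similarity of two pre-normalized phrases on a 0-100 scale."""
    if a > b:  # canonical ordering: symmetric function, better cache reuse
        a, b = b, a
    return _similarity_cached(a, b)


def tokenize(text: str) -> list[str]:
    """Split text into normalized word tokens plus sentence-boundary tokens.

    ``.``, ``;`` and newlines survive as standalone boundary tokens so the
    negation scoper can stop at sentence breaks; every other token is run
    through :func:`normalize_term`.
    """
    tokens: list[str] = []
    for raw in _TOKEN_RE.findall(text):
        if raw == "\n" or raw in BOUNDARY_TOKENS:
            tokens.append("\n" if raw == "\n" else raw)
            continue
        word = normalize_term(raw)
        if word:
            tokens.extend(word.split())
    return tokens


@dataclass(frozen=True)
class SymptomMatch:
    concept: str
    matched_text: str
    similarity: float
    negated: bool
    token_start: int
    token_end: int

    def __post_init__(self) -> None:
        if not self.token_start < self.token_end:
            raise ValueError("token_start must be < token_end")


@dataclass(frozen=True)
class ExtractionResult:
    doc_id: str
    matches: tuple[SymptomMatch, ...]
    symptoms_present: frozenset[str]
    passage_found: bool

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "passage_found": self.passage_found,
            "symptoms_present": sorted(self.symptoms_present),
            "matches": [
                {
                    "concept": m.concept,
                    "matched_text": m.matched_text,
                    "similarity": round(m.similarity, 4),
                    "negated": m.negated,
                    "token_start": m.token_start,
                    "token_end": m.token_end,
                }
                for m in self.matches
            ],
        }


def detect_negation(
    tokens: Sequence[str], match_start: int, config: NegationConfig = NegationConfig()
) -> bool:
    """True iff a cue token occurs within ``window_tokens`` tokens immediately
    before ``match_start``, not crossing a sentence boundary when bounded."""
    if not 0 <= match_start < len(tokens):
        raise ValueError("match_start out of range")
    lo = max(0, match_start - config.window_tokens)
    for i in range(match_start - 1, lo - 1, -1):
        tok = tokens[i]
        if tok in BOUNDARY_TOKENS:
            if config.sentence_bounded:
                return False
            continue
        if tok in config.cue_terms:
            return True
    return False


def _candidate_windows(tokens: Sequence[str], k: int) -> list[tuple[int, str]]:
    """All k-token windows of word tokens that do not span a sentence boundary."""
    out = []
    n = len(tokens)
    for i in range(n - k + 1):
        window = tokens[i : i + k]
        if any(t in BOUNDARY_TOKENS for t in window):
            continue
        out.append((i, " ".join(window)))
    return out


def match_symptoms(
    passage: Union[Passage, str],
    lexicon: Sequence[SymptomConcept],
    threshold: float = 80.0,
    negation: NegationConfig = NegationConfig(),
) -> list[SymptomMatch]:
    """Fuzzy-match lexicon synonyms against a passage.

    For each k-token synonym a k-token window slides over the passage; windows
    scoring at or above ``threshold`` become matches.  Overlapping windows that
    hit the same concept are merged into the single best-scoring match, and
    every emitted match carries its negation flag.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if not lexicon:
        log.warning("match_symptoms called with an empty lexicon")
        return []
    text = passage.text if isinstance(passage, Passage) else passage
    tokens = tokenize(text)
    if not tokens:
        return []

    windows_by_k: dict[int, list[tuple[int, str]]] = {}
    # collect raw candidates per concept, then merge overlaps
    per_concept: dict[str, list[tuple[float, int, int, str]]] = {}
    max_gap = 1.0 - threshold / 100.0
    for concept in lexicon:
        for synonym in concept.synonyms:
            k = len(synonym.split())
            if k not in windows_by_k:
                windows_by_k[k] = _candidate_windows(tokens, k)
            ls = len(synonym)
            for start, window in windows_by_k[k]:
                longest = max(len(window), ls)
                if abs(len(window) - ls) > max_gap * longest:
                    continue  # similarity cannot reach threshold
                score = similarity(window, synonym)
                if score >= threshold:
                    per_concept.setdefault(concept.canonical_name, []).append(
                        (score, start, start + k, window)
                    )

    matches: list[SymptomMatch] = []
    for name, candidates in per_concept.items():
        candidates.sort(key=lambda c: (c[1], -c[0], c[2]))
        # merge chains of overlapping candidate spans, keep the best of each
        group: list[tuple[float, int, int, str]] = []
        group_end = -1
        for cand in candidates:
            if group and cand[1] < group_end:
                group.append(cand)
                group_end = max(group_end, cand[2])
            else:
                if group:
                    matches.append(_best_match(name, group, tokens, negation))
                group = [cand]
                group_end = cand[2]
        if group:
            matches.append(_best_match(name, group, tokens, negation))

    matches.sort(key=lambda m: (m.token_start, m.concept))
    return matches


def _best_match(
    name: str,
    group: list[tuple[float, int, int, str]],
    tokens: Sequence[str],
    negation: NegationConfig,
) -> SymptomMatch:
    score, start, end, window = max(group, key=lambda c: (c[0], -c[1], c[2] - c[1]))
    return SymptomMatch(
        concept=name,
        matched_text=window,
        similarity=score,
        negated=detect_negation(tokens, start, negation),
        token_start=start,
        token_end=end,
    )


def extract_patient_symptoms(
    doc: DischargeSummary,
    lexicon: Sequence[SymptomConcept],
    threshold: float = 80.0,
    negation: NegationConfig = NegationConfig(),
) -> ExtractionResult:
    """Full per-document model: passage isolation, fuzzy matching, negation.

    A concept is present when it has at least one non-negated match; documents
    without a presenting passage yield an empty result with
    ``passage_found=False``.
    """
    passage = extract_presenting_passage(doc)
    if passage is None:
        return ExtractionResult(doc.doc_id, (), frozenset(), False)
    matches = match_symptoms(passage, lexicon, threshold, negation)
    present = frozenset(m.concept for m in matches if not m.negated)
    return ExtractionResult(doc.doc_id, tuple(matches), present, True)


def extract_corpus_symptoms(
    docs: Iterable[DischargeSummary],
    lexicon: Sequence[SymptomConcept],
    threshold: float = 80.0,
    negation: NegationConfig = NegationConfig(),
) -> dict[str, ExtractionResult]:
    return {
        doc.doc_id: extract_patient_symptoms(doc, lexicon, threshold, negation)
        for doc in docs
    }
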
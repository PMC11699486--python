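"""Synthetic discharge-summary corpora with matched ground truth.

The generator is the fixture engine for the whole pipeline: it draws patient
metadata, symptom sets and medication sets from configurable per-gender
probabilities, renders heterogeneous document layouts (heading-led passage,
trigger-phrase preamble, one-symptom-per-line table), and can corrupt mention
words with single-character typos and wrap mentions in negation cues drawn
from the same cue vocabulary the extractor uses.

Default prevalences reproduce the per-gender symptom and drug-class rates of
the reference cohort (symptom denominators: 1061 women / 2278 men; overall
women fraction 1769/5358), so a generated corpus statistically mirrors it.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from .docparse import DischargeSummary
from .lexicon import (
    BUILTIN,
    DRUG_CLASSES,
    MedicationEntry,
    NegationConfig,
    SymptomConcept,
    load_medication_dictionary,
    load_symptom_lexicon,
)

__all__ = [
    "DEFAULT_SYMPTOM_PREVALENCE",
    "DEFAULT_MEDICATION_PROB",
    "DEFAULT_PROP_WOMEN",
    "CovariateModel",
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "inject_typo",
    "evaluate_extraction",
    "write_truth",
    "read_truth",
]

#: Per-gender presenting-symptom rates among symptomatic admissions
#: (women n=1061, men n=2278 in the reference cohort).
DEFAULT_SYMPTOM_PREVALENCE: dict[str, dict[str, float]] = {
    "woman": {
        "chest pain": 597 / 1061,
        "shortness of breath": 525 / 1061,
        "nausea or vomiting": 105 / 1061,
        "sweating or diaphoresis": 58 / 1061,
        "abdominal pain or discomfort": 83 / 1061,
        "arm pain": 36 / 1061,
        "ghabrahat": 54 / 1061,
        "weakness": 38 / 1061,
        "shoulder pain": 30 / 1061,
        "palpitations": 28 / 1061,
        "back pain": 23 / 1061,
        "altered mental status": 15 / 1061,
        "dizziness": 14 / 1061,
        "jaw pain": 15 / 1061,
        "orthopnea": 14 / 1061,
        "neck pain": 7 / 1061,
        "throat pain": 0.0,
        "swelling": 1 / 1061,
    },
    "man": {
        "chest pain": 1567 / 2278,
        "shortness of breath": 859 / 2278,
        "nausea or vomiting": 124 / 2278,
        "sweating or diaphoresis": 167 / 2278,
        "abdominal pain or discomfort": 107 / 2278,
        "arm pain": 91 / 2278,
        "ghabrahat": 84 / 2278,
        "weakness": 57 / 2278,
        "shoulder pain": 63 / 2278,
        "palpitations": 43 / 2278,
        "back pain": 36 / 2278,
        "altered mental status": 42 / 2278,
        "dizziness": 29 / 2278,
        "jaw pain": 14 / 2278,
        "orthopnea": 18 / 2278,
        "neck pain": 9 / 2278,
        "throat pain": 4 / 2278,
        "swelling": 0.0,
    },
}

#: Per-gender discharge prescription rates consistent with the reference
#: cohort's overall rates and univariate gender odds ratios.
DEFAULT_MEDICATION_PROB: dict[str, dict[str, float]] = {
    "woman": {
        "aspirin": 0.9410,
        "statin": 0.8966,
        "clopidogrel": 0.8180,
        "beta_blocker": 0.7368,
        "antidiabetic": 0.4849,
        "ace_inhibitor": 0.3464,
        "arb": 0.1656,
        "aspirin_clopidogrel_combo": 0.0099,
        "ticagrelor": 0.0014,
    },
    "man": {
        "aspirin": 0.9489,
        "statin": 0.9333,
        "clopidogrel": 0.8669,
        "beta_blocker": 0.8187,
        "antidiabetic": 0.3840,
        "ace_inhibitor": 0.4141,
        "arb": 0.1079,
        "aspirin_clopidogrel_combo": 0.0083,
        "ticagrelor": 0.0003,
    },
}

DEFAULT_PROP_WOMEN = 1769 / 5358

_TEMPLATES = ("heading", "trigger", "table", "none")

_DISTRACTOR_ROWS = (
    "Tab Amiodarone 200mg OD",
    "Inj Clexane 40mg SC OD",
    "Tab Lasix 40mg OD",
    "Syp Mucaine 10ml TDS",
)

_COURSE = (
    "Patient was admitted and managed as per protocol. Serial cardiac "
    "enzymes and ECGs were monitored. Patient remained stable and was "
    "discharged in satisfactory condition."
)

_NEUTRAL_COMPLAINT = "Brought for further evaluation."

_INSULIN_NAMES = frozenset({"insulin", "mixtard", "humulin"})


class CovariateModel(BaseModel):
    """Metadata distributions for generated patients."""

    diabetes_prob: float = Field(0.40, ge=0.0, le=1.0)
    pci_prob: float = Field(0.50, ge=0.0, le=1.0)
    age_mean_women: float = 67.8
    age_mean_men: float = 63.3
    age_sd: float = Field(12.0, gt=0.0)
    year_range: tuple[int, int] = (2010, 2018)

    @model_validator(mode="after")
    def _check_years(self) -> "CovariateModel":
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (low, high) with low <= high")
        return self


class GeneratorConfig(BaseModel):
    """Everything the corpus generator needs; a fixed seed makes the output
    byte-identical across runs."""

    n_patients: int = Field(gt=0)
    prop_women: float = Field(DEFAULT_PROP_WOMEN, gt=0.0, lt=1.0)
    symptom_prevalence: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SYMPTOM_PREVALENCE.items()}
    )
    medication_prob: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_MEDICATION_PROB.items()}
    )
    covariate_model: CovariateModel = Field(default_factory=CovariateModel)
    typo_rate: float = Field(0.0, ge=0.0, le=1.0)
    negation_rate: float = Field(0.0, ge=0.0, le=1.0)
    distractor_prob: float = Field(0.1, ge=0.0, le=1.0)
    template_mix: dict[str, float] = Field(
        default_factory=lambda: {"heading": 0.5, "trigger": 0.3, "table": 0.2, "none": 0.0}
    )
    seed: int = 0

    @field_validator("symptom_prevalence", "medication_prob")
    @classmethod
    def _check_probs(cls, value: dict) -> dict:
        for gender, probs in value.items():
            if gender not in ("woman", "man"):
                raise ValueError(f"prevalence keyed by unknown gender {gender!r}")
            for name, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {name!r} out of [0, 1]: {p}")
        return value

    @field_validator("template_mix")
    @classmethod
    def _check_mix(cls, value: dict[str, float]) -> dict[str, float]:
        unknown = set(value) - set(_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")
        if any(w < 0 for w in value.values()):
            raise ValueError("template weights must be non-negative")
        total = sum(value.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template weights must sum to 1, got {total}")
        return value


@dataclass(frozen=True)
class GroundTruth:
    doc_id: str
    true_symptoms: frozenset[str]
    negated_mentions: frozenset[str]
    true_drug_classes: frozenset[str]
    gender: str
    age_years: float
    admission_year: int
    diabetes: bool
    pci: bool

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "true_symptoms": sorted(self.true_symptoms),
            "negated_mentions": sorted(self.negated_mentions),
            "true_drug_classes": sorted(self.true_drug_classes),
            "gender": self.gender,
            "age_years": self.age_years,
            "admission_year": self.admission_year,
            "diabetes": self.diabetes,
            "pci": self.pci,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GroundTruth":
        return cls(
            doc_id=str(obj["doc_id"]),
            true_symptoms=frozenset(obj["true_symptoms"]),
            negated_mentions=frozenset(obj["negated_mentions"]),
            true_drug_classes=frozenset(obj["true_drug_classes"]),
            gender=str(obj["gender"]),
            age_years=float(obj["age_years"]),
            admission_year=int(obj["admission_year"]),
            diabetes=bool(obj["diabetes"]),
            pci=bool(obj["pci"]),
        )


def inject_typo(word: str, rng: random.Random) -> str:
    """Apply exactly one random character edit (substitute/delete/insert).

    Words shorter than two characters are returned unchanged; otherwise the
    result is guaranteed to sit at edit distance 1 from the input.
    """
    if len(word) < 2:
        return word
    op = rng.choice(("substitute", "delete", "insert"))
    letters = string.ascii_lowercase
    if op == "substitute":
        pos = rng.randrange(len(word))
        choices = [c for c in letters if c != word[pos]]
        return word[:pos] + rng.choice(choices) + word[pos + 1 :]
    if op == "delete":
        pos = rng.randrange(len(word))
        return word[:pos] + word[pos + 1 :]
    pos = rng.randrange(len(word) + 1)
    return word[:pos] + rng.choice(letters) + word[pos:]


def _corrupt(phrase: str, rate: float, rng: random.Random) -> str:
    if rate <= 0.0:
        return phrase
    words = [
        inject_typo(w, rng) if rng.random() < rate else w for w in phrase.split()
    ]
    return " ".join(words)


def _join_list(items: Sequence[str]) -> str:
    if len(items) == 1:
        return items[0]
    return ", ".join(items[:-1]) + " and " + items[-1]


_NEGATION_FRAMES = ("No {}.", "Not {}.", "Denies {}.", "Without {}.")


def _render_document(
    template: str,
    gender: str,
    age: float,
    affirmed: Sequence[str],
    negated: Sequence[str],
    med_rows: Sequence[str],
    rng: random.Random,
) -> str:
    neg_sentences = " ".join(
        rng.choice(_NEGATION_FRAMES).format(m) for m in negated
    )
    parts: list[str] = ["DISCHARGE SUMMARY\n\n"]

    if template == "heading":
        if affirmed or negated:
            complaint = f"Patient presented with {_join_list(affirmed)}." if affirmed else ""
            body = " ".join(s for s in (complaint, neg_sentences) if s)
        else:
            body = _NEUTRAL_COMPLAINT
        parts.append(f"PRESENTING COMPLAINTS:\n{body}\n\n")
    elif template == "table":
        lines = list(affirmed) + [f"no {m}" for m in negated]
        body = "\n".join(lines) if lines else _NEUTRAL_COMPLAINT
        parts.append(f"PRESENTING COMPLAINTS:\n{body}\n\n")
    elif template == "trigger":
        intro = f"This {int(age)} year old {gender}"
        if affirmed:
            complaint = f"{intro} presented with {_join_list(affirmed)}."
        else:
            complaint = f"{intro} presented with nonspecific complaints."
        body = " ".join(s for s in (complaint, neg_sentences) if s)
        parts = [f"{body}\n\n"]  # trigger docs start with the preamble
    else:  # "none": no presenting passage at all
        parts.append("ADMISSION NOTE:\nRecords incomplete.\n\n")

    parts.append(f"HOSPITAL COURSE:\n{_COURSE}\n\n")
    if med_rows:
        parts.append("DISCHARGE MEDICATIONS:\n" + "\n".join(med_rows) + "\n\n")
    parts.append("FOLLOW UP:\nReview in clinic in two weeks.\n")
    return "".join(parts)


def _medication_row(name: str, drug_class: str, rng: random.Random) -> str:
    display = name.title()
    if drug_class == "aspirin_clopidogrel_combo":
        return f"Tab {display} 75/75 OD"
    if name in _INSULIN_NAMES:
        return f"Inj {display} {rng.choice((10, 20, 30))} units SC BD"
    dose = rng.choice((5, 10, 20, 25, 40, 50, 75, 150, 500))
    freq = rng.choice(("OD", "BD", "TDS"))
    return f"Tab {display} {dose}mg {freq}"


def generate_corpus(
    config: GeneratorConfig,
    lexicon: Optional[Sequence[SymptomConcept]] = None,
    dictionary: Optional[Mapping[str, MedicationEntry]] = None,
) -> tuple[list[DischargeSummary], list[GroundTruth]]:
    """Generate a corpus and its matched ground truth.

    Mentions are rendered using synonyms from ``lexicon`` (builtin by
    default); medication rows use names from ``dictionary``.  A single random
    stream seeded by ``config.seed`` is advanced in document order.
    """
    lexicon = list(lexicon) if lexicon is not None else load_symptom_lexicon(BUILTIN)
    dictionary = dictionary if dictionary is not None else load_medication_dictionary(BUILTIN)
    concepts = {c.canonical_name: c for c in lexicon}
    class_names: dict[str, list[str]] = {c: [] for c in DRUG_CLASSES}
    for name, entry in dictionary.items():
        if entry.drug_class in class_names:
            class_names[entry.drug_class].append(name)
    for names in class_names.values():
        names.sort()

    rng = random.Random(config.seed)
    cov = config.covariate_model
    templates = sorted(config.template_mix)
    weights = [config.template_mix[t] for t in templates]

    docs: list[DischargeSummary] = []
    truths: list[GroundTruth] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        doc_id = f"synth-{i:0{width}d}"
        gender = "woman" if rng.random() < config.prop_women else "man"
        age_mean = cov.age_mean_women if gender == "woman" else cov.age_mean_men
        age = max(19.0, round(rng.gauss(age_mean, cov.age_sd), 1))
        year = rng.randint(*cov.year_range)
        diabetes = rng.random() < cov.diabetes_prob
        pci = rng.random() < cov.pci_prob

        mentioned = [
            name
            for name, p in config.symptom_prevalence.get(gender, {}).items()
            if name in concepts and rng.random() < p
        ]
        negated = [m for m in mentioned if rng.random() < config.negation_rate]
        affirmed = [m for m in mentioned if m not in negated]

        def _mention(concept_name: str) -> str:
            synonym = rng.choice(concepts[concept_name].synonyms)
            return _corrupt(synonym, config.typo_rate, rng)

        affirmed_text = [_mention(m) for m in affirmed]
        negated_text = [_mention(m) for m in negated]

        true_classes = [
            c
            for c, p in config.medication_prob.get(gender, {}).items()
            if class_names.get(c) and rng.random() < p
        ]
        med_rows = [
            _medication_row(rng.choice(class_names[c]), c, rng) for c in true_classes
        ]
        if rng.random() < config.distractor_prob:
            med_rows.append(rng.choice(_DISTRACTOR_ROWS))
        rng.shuffle(med_rows)

        template = rng.choices(templates, weights=weights, k=1)[0]
        text = _render_document(
            template, gender, age, affirmed_text, negated_text, med_rows, rng
        )
        docs.append(
            DischargeSummary(
                doc_id=doc_id,
                text=text,
                gender=gender,
                age_years=age,
                admission_year=year,
                diabetes=diabetes,
                pci=pci,
            )
        )
        truths.append(
            GroundTruth(
                doc_id=doc_id,
                true_symptoms=frozenset(affirmed),
                negated_mentions=frozenset(negated),
                true_drug_classes=frozenset(true_classes),
                gender=gender,
                age_years=age,
                admission_year=year,
                diabetes=diabetes,
                pci=pci,
            )
        )
    return docs, truths


def write_truth(truths: Iterable[GroundTruth], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps(t.to_dict()) + "\n")


def read_truth(path: Union[str, Path]) -> list[GroundTruth]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(GroundTruth.from_dict(json.loads(line)))
    return out


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}


def evaluate_extraction(
    truths: Sequence[GroundTruth],
    predictions: Mapping[str, Iterable[str]],
    field: str = "symptoms",
) -> dict:
    """Per-concept and micro-averaged precision/recall/F1 of predicted label
    sets against ground truth.

    ``predictions`` maps doc_id to the predicted label set (canonical symptom
    names, or drug classes with ``field="medications"``).  Document keys must
    coincide exactly.
    """
    if field not in ("symptoms", "medications"):
        raise ValueError("field must be 'symptoms' or 'medications'")
    truth_by_id = {t.doc_id: t for t in truths}
    if set(truth_by_id) != set(predictions):
        missing = sorted(set(truth_by_id) ^ set(predictions))
        raise ValueError(f"doc_id mismatch between truth and predictions: {missing[:5]}")

    counts: dict[str, list[int]] = {}
    for doc_id, truth in truth_by_id.items():
        true_set = (
            set(truth.true_symptoms) if field == "symptoms" else set(truth.true_drug_classes)
        )
        pred_set = set(predictions[doc_id])
        for label in true_set | pred_set:
            tp_fp_fn = counts.setdefault(label, [0, 0, 0])
            if label in true_set and label in pred_set:
                tp_fp_fn[0] += 1
            elif label in pred_set:
                tp_fp_fn[1] += 1
            else:
                tp_fp_fn[2] += 1

    per_concept = {
        label: _prf(tp, fp, fn) for label, (tp, fp, fn) in sorted(counts.items())
    }
    tp = sum(v[0] for v in counts.values())
    fp = sum(v[1] for v in counts.values())
    fn = sum(v[2] for v in counts.values())
    return {"per_concept": per_concept, "micro": _prf(tp, fp, fn)}
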
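"""Cohort assembly and gender-disparity statistics.

Univariate odds ratios use the cross-product estimate with Woolf (log-normal)
confidence intervals; any zero cell makes the estimate "omitted" rather than
continuity-corrected.  Adjusted odds ratios come from a Newton-type
maximum-likelihood logistic regression written out explicitly so convergence
behavior and Wald intervals are fully specified.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .docparse import DischargeSummary
from .lexicon import DRUG_CLASSES
from .meds import MedicationExtraction
from .symptoms import ExtractionResult

__all__ = [
    "AGE_CUTOFF",
    "PatientRecord",
    "ContingencyTable2x2",
    "ORResult",
    "FlowCounts",
    "build_cohort",
    "contingency",
    "odds_ratio_univariate",
    "chi_square",
    "mann_whitney",
    "odds_ratio_adjusted",
    "render_tables",
]

log = logging.getLogger(__name__)

#: Age dichotomy used by the adjusted symptom models.
AGE_CUTOFF = 45.0


class CohortError(ValueError):
    """Raised on irreconcilable cohort inputs."""


@dataclass(frozen=True)
class PatientRecord:
    doc_id: str
    gender: str
    age_years: float
    admission_year: int
    diabetes: bool
    pci: bool
    symptoms: Mapping[str, bool]
    medications: Mapping[str, bool]
    symptoms_found: bool
    meds_found: bool

    @property
    def age_group(self) -> str:
        return "under_45" if self.age_years < AGE_CUTOFF else "over_45"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with exposure = woman, outcome = indicator present.

    a: women with outcome, b: women without, c: men with, d: men without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ORResult:
    or_point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    method: str  # univariate_woolf | logistic_adjusted
    omitted: bool = False
    omitted_reason: Optional[str] = None


@dataclass(frozen=True)
class FlowCounts:
    total: int
    with_symptoms: int
    without_symptoms: int
    with_meds: int
    without_meds: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "with_symptoms": self.with_symptoms,
            "without_symptoms": self.without_symptoms,
            "with_meds": self.with_meds,
            "without_meds": self.without_meds,
        }


def build_cohort(
    docs: Sequence[DischargeSummary],
    symptom_results: Mapping[str, ExtractionResult],
    medication_results: Mapping[str, MedicationExtraction],
    symptom_names: Optional[Sequence[str]] = None,
) -> tuple[list[PatientRecord], FlowCounts]:
    """Join metadata with extraction outputs and tally the flow accounting.

    Extraction results referencing unknown doc_ids are a reconciliation error;
    documents without an extraction result are treated as not-found for that
    extraction.
    """
    known = {d.doc_id for d in docs}
    stray = sorted((set(symptom_results) | set(medication_results)) - known)
    if stray:
        raise CohortError(f"extraction results reference unknown doc_ids: {stray}")
    if symptom_names is None:
        names: set[str] = set()
        for res in symptom_results.values():
            names.update(m.concept for m in res.matches)
            names.update(res.symptoms_present)
        symptom_names = sorted(names)

    records: list[PatientRecord] = []
    n_sym = n_med = 0
    for doc in docs:
        sym = symptom_results.get(doc.doc_id)
        med = medication_results.get(doc.doc_id)
        symptoms_found = sym is not None and sym.passage_found
        meds_found = med is not None and med.meds_found
        present = sym.symptoms_present if sym is not None else frozenset()
        classified = med.classified if med is not None else frozenset()
        if present:
            n_sym += 1
        if meds_found:
            n_med += 1
        records.append(
            PatientRecord(
                doc_id=doc.doc_id,
                gender=doc.gender,
                age_years=doc.age_years,
                admission_year=doc.admission_year,
                diabetes=doc.diabetes,
                pci=doc.pci,
                symptoms={s: s in present for s in symptom_names},
                medications={c: c in classified for c in DRUG_CLASSES},
                symptoms_found=symptoms_found,
                meds_found=meds_found,
            )
        )
    flow = FlowCounts(
        total=len(records),
        with_symptoms=n_sym,
        without_symptoms=len(records) - n_sym,
        with_meds=n_med,
        without_meds=len(records) - n_med,
    )
    return records, flow


def _outcome_subset(
    cohort: Sequence[PatientRecord], outcome: str, symptomatic_only: bool
) -> tuple[list[PatientRecord], str]:
    if outcome in DRUG_CLASSES:
        return [r for r in cohort if r.meds_found], "medications"
    if any(outcome in r.symptoms for r in cohort):
        subset = [r for r in cohort if r.symptoms_found] if symptomatic_only else list(cohort)
        return subset, "symptoms"
    raise CohortError(f"unknown outcome {outcome!r}")


def contingency(
    cohort: Sequence[PatientRecord], outcome: str, symptomatic_only: bool = True
) -> ContingencyTable2x2:
    """2x2 gender-by-outcome counts over records where the relevant extraction
    found content (documents with a presenting passage for symptoms, documents
    with classified medication rows for drug classes)."""
    subset, kind = _outcome_subset(cohort, outcome, symptomatic_only)
    a = b = c = d = 0
    for rec in subset:
        value = (rec.symptoms if kind == "symptoms" else rec.medications).get(outcome, False)
        if rec.gender == "woman":
            if value:
                a += 1
            else:
                b += 1
        else:
            if value:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio_univariate(
    table: ContingencyTable2x2, alpha: float = 0.05
) -> ORResult:
    """Cross-product odds ratio with a Woolf confidence interval.

    Any zero cell yields ``omitted=True`` with no estimate, mirroring how
    degenerate rows are reported rather than continuity-corrected.
    """
    if table.has_zero_cell():
        return ORResult(None, None, None, None, "univariate_woolf", True, "zero cell")
    a, b, c, d = table.a, table.b, table.c, table.d
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return ORResult(or_point, ci_low, ci_high, float(p), "univariate_woolf")


def chi_square(table: ContingencyTable2x2) -> tuple[float, Optional[float]]:
    """Pearson chi-square (no continuity correction) on the 2x2 table.

    A zero margin makes the statistic undefined: returns (nan, None) with a
    warning rather than raising.
    """
    obs = table.as_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        warnings.warn("chi-square undefined for a table with a zero margin")
        return float("nan"), None
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of two samples.

    Exact distribution when both groups have <= 20 observations and no ties;
    tie-corrected normal approximation (no continuity correction) otherwise.
    """
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = list(values_a) + list(values_b)
    has_ties = len(set(pooled)) < len(pooled)
    if max(len(values_a), len(values_b)) <= 20 and not has_ties:
        res = sps.mannwhitneyu(values_a, values_b, method="exact")
    else:
        res = sps.mannwhitneyu(
            values_a, values_b, method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# adjusted models


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Newton-Raphson logistic MLE; returns (beta, covariance) or None.

    Convergence when the maximum absolute score drops below ``tol``; failure
    to converge (including divergence under separation) returns None.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < tol:
            if np.max(np.abs(beta)) > 30.0:
                return None  # "converged" onto the separation boundary
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                return None
            return beta, cov
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            return None
        # halve overly aggressive steps to keep Newton stable
        while np.max(np.abs(step)) > 10.0:
            step = step / 2.0
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            return None
    return None


_COVARIATE_COLUMNS = {
    "diabetes": lambda r: float(r.diabetes),
    "pci": lambda r: float(r.pci),
    "age_group": lambda r: float(r.age_years < AGE_CUTOFF),
    "age_years": lambda r: float(r.age_years),
    "admission_year": lambda r: float(r.admission_year),
}


def odds_ratio_adjusted(
    cohort: Sequence[PatientRecord],
    outcome: str,
    covariates: Sequence[str],
    alpha: float = 0.05,
    symptomatic_only: bool = True,
) -> ORResult:
    """Gender odds ratio from ``outcome ~ gender + covariates`` logistic MLE.

    Covariate encodings: diabetes/pci binary, age_group binary at the age-45
    cutoff, admission_year centered and continuous.  Returns exp of the gender
    coefficient with a Wald interval; degenerate outcomes, non-convergence and
    constant-column collinearity produce omitted results, never exceptions.
    """
    unknown = [c for c in covariates if c not in _COVARIATE_COLUMNS]
    if unknown:
        raise CohortError(f"unknown covariates: {unknown}")
    subset, kind = _outcome_subset(cohort, outcome, symptomatic_only)
    if not subset:
        return ORResult(None, None, None, None, "logistic_adjusted", True, "empty cohort")
    y = np.array(
        [
            float((r.symptoms if kind == "symptoms" else r.medications).get(outcome, False))
            for r in subset
        ]
    )
    if y.min() == y.max():
        return ORResult(
            None, None, None, None, "logistic_adjusted", True, "degenerate outcome"
        )
    cols = [np.ones(len(subset)), np.array([float(r.gender == "woman") for r in subset])]
    for name in covariates:
        col = np.array([_COVARIATE_COLUMNS[name](r) for r in subset])
        if name in ("admission_year", "age_years"):
            col = col - col.mean()
        if col.std() == 0.0:
            log.debug("dropping constant covariate %r", name)
            continue
        cols.append(col)
    X = np.column_stack(cols)
    fit = _fit_logistic(X, y)
    if fit is None:
        return ORResult(
            None, None, None, None, "logistic_adjusted", True,
            "model failed to converge (possible separation)",
        )
    beta, cov = fit
    b, var = beta[1], cov[1, 1]
    if var <= 0:
        return ORResult(
            None, None, None, None, "logistic_adjusted", True, "singular information"
        )
    se = math.sqrt(var)
    if not math.isfinite(se) or se > 50.0:
        return ORResult(
            None, None, None, None, "logistic_adjusted", True,
            "unstable estimate (near-empty cell)",
        )
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(b) / se)
    return ORResult(
        math.exp(b), math.exp(b - z * se), math.exp(b + z * se), float(p),
        "logistic_adjusted",
    )


# ---------------------------------------------------------------------------
# table rendering


def _fmt_or(res: ORResult, decimals: int = 2) -> tuple[str, str, str]:
    if res.omitted:
        return "Omitted", "", ""
    fmt = f"{{:.{decimals}f}}"
    return (
        fmt.format(res.or_point),
        f"{fmt.format(res.ci_low)}-{fmt.format(res.ci_high)}",
        _fmt_p(res.p_value),
    )


def _fmt_p(p: Optional[float]) -> str:
    if p is None or math.isnan(p):
        return ""
    return "<.001" if p < 0.001 else f"{p:.2f}".lstrip("0") or "0"


def render_tables(
    cohort: Sequence[PatientRecord],
    symptom_covariates: Sequence[str] = ("diabetes", "age_group"),
    medication_covariates: Sequence[str] = ("diabetes", "pci", "admission_year"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the three reporting tables.

    Returns (symptom frequency table, adjusted-symptom table, medication
    table), each ordered by descending total frequency.  Percentages carry two
    decimals in the frequency table and one decimal in the OR tables.
    """
    symptom_names = sorted({s for r in cohort for s in r.symptoms})
    sym_cohort = [r for r in cohort if r.symptoms_found]
    med_cohort = [r for r in cohort if r.meds_found]
    n_w = sum(r.gender == "woman" for r in sym_cohort)
    n_m = len(sym_cohort) - n_w

    freq_rows, adj_rows = [], []
    for name in symptom_names:
        table = contingency(cohort, name, symptomatic_only=True)
        total = table.a + table.c
        _, p = chi_square(table)
        freq_rows.append(
            {
                "symptom": name,
                "total_n": total,
                "total_pct": round(100 * total / len(sym_cohort), 2) if sym_cohort else 0.0,
                "women_n": table.a,
                "women_pct": round(100 * table.a / n_w, 2) if n_w else 0.0,
                "men_n": table.c,
                "men_pct": round(100 * table.c / n_m, 2) if n_m else 0.0,
                "p_value": _fmt_p(p) if p is not None else "",
            }
        )
        uni = odds_ratio_univariate(table)
        adj = odds_ratio_adjusted(cohort, name, symptom_covariates)
        u_or, u_ci, u_p = _fmt_or(uni)
        a_or, a_ci, a_p = _fmt_or(adj)
        adj_rows.append(
            {
                "symptom": name,
                "total_n": total,
                "total_pct": round(100 * total / len(sym_cohort), 1) if sym_cohort else 0.0,
                "univariate_or": u_or,
                "univariate_ci": u_ci,
                "univariate_p": u_p,
                "adjusted_or": a_or,
                "adjusted_ci": a_ci,
                "adjusted_p": a_p,
            }
        )

    med_rows = []
    for name in DRUG_CLASSES:
        table = contingency(cohort, name, symptomatic_only=False)
        total = table.a + table.c
        uni = odds_ratio_univariate(table)
        adj = odds_ratio_adjusted(cohort, name, medication_covariates)
        u_or, u_ci, u_p = _fmt_or(uni)
        a_or, a_ci, a_p = _fmt_or(adj)
        med_rows.append(
            {
                "drug_class": name,
                "total_n": total,
                "total_pct": round(100 * total / len(med_cohort), 1) if med_cohort else 0.0,
                "univariate_or": u_or,
                "univariate_ci": u_ci,
                "univariate_p": u_p,
                "adjusted_or": a_or,
                "adjusted_ci": a_ci,
                "adjusted_p": a_p,
            }
        )

    freq = pd.DataFrame(
        freq_rows,
        columns=["symptom", "total_n", "total_pct", "women_n", "women_pct", "men_n", "men_pct", "p_value"],
    )
    adj = pd.DataFrame(
        adj_rows,
        columns=["symptom", "total_n", "total_pct", "univariate_or", "univariate_ci", "univariate_p", "adjusted_or", "adjusted_ci", "adjusted_p"],
    )
    med = pd.DataFrame(
        med_rows,
        columns=["drug_class", "total_n", "total_pct", "univariate_or", "univariate_ci", "univariate_p", "adjusted_or", "adjusted_ci", "adjusted_p"],
    )
    for df in (freq, adj, med):
        if len(df):
            df.sort_values("total_n", ascending=False, inplace=True, kind="mergesort")
            df.reset_index(drop=True, inplace=True)
    return freq, adj, med
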
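import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardext.meds import MedicationExtraction
from cardext.stats import (
    CohortError,
    ContingencyTable2x2,
    PatientRecord,
    build_cohort,
    chi_square,
    contingency,
    mann_whitney,
    odds_ratio_adjusted,
    odds_ratio_univariate,
    render_tables,
)
from cardext.symptoms import ExtractionResult

from .conftest import make_doc

cells = st.integers(min_value=1, max_value=500)


def make_record(
    doc_id="r1",
    gender="woman",
    age=60.0,
    year=2015,
    diabetes=False,
    pci=False,
    symptoms=None,
    medications=None,
    symptoms_found=True,
    meds_found=True,
):
    return PatientRecord(
        doc_id=doc_id,
        gender=gender,
        age_years=age,
        admission_year=year,
        diabetes=diabetes,
        pci=pci,
        symptoms=symptoms or {},
        medications=medications or {},
        symptoms_found=symptoms_found,
        meds_found=meds_found,
    )


def synthetic_cohort(a, b, c, d, outcome="chest pain", rng=None):
    """Cohort with exactly the given gender-by-outcome counts."""
    rng = rng or random.Random(0)
    records = []
    for gender, with_outcome, without in (("woman", a, b), ("man", c, d)):
        for has in [True] * with_outcome + [False] * without:
            records.append(
                make_record(
                    doc_id=f"r{len(records)}",
                    gender=gender,
                    age=rng.uniform(30, 85),
                    diabetes=rng.random() < 0.4,
                    symptoms={outcome: has},
                )
            )
    return records


class TestBuildCohort:
    def _docs(self, n=3):
        return [make_doc("text", doc_id=f"d{i}") for i in range(n)]

    def _sym(self, doc_id, present, found=True):
        return ExtractionResult(doc_id, (), frozenset(present), found)

    def _med(self, doc_id, classified):
        return MedicationExtraction(
            doc_id, len(classified), frozenset(classified), (), bool(classified)
        )

    def test_flow_counts(self):
        docs = self._docs(3)
        sym = {
            "d0": self._sym("d0", {"chest pain"}),
            "d1": self._sym("d1", {"weakness"}),
            "d2": self._sym("d2", set()),
        }
        cohort, flow = build_cohort(docs, sym, {})
        assert flow.total == 3
        assert flow.with_symptoms == 2
        assert flow.without_symptoms == 1
        assert flow.with_meds == 0
        assert flow.without_meds == 3
        assert flow.with_symptoms + flow.without_symptoms == flow.total

    def test_empty_corpus(self):
        cohort, flow = build_cohort([], {}, {})
        assert cohort == []
        assert flow.to_dict() == dict.fromkeys(flow.to_dict(), 0)

    def test_reconciliation_error(self):
        docs = self._docs(1)
        with pytest.raises(CohortError, match="ghost"):
            build_cohort(docs, {"ghost": self._sym("ghost", set())}, {})

    def test_indicators_joined(self):
        docs = self._docs(2)
        sym = {"d0": self._sym("d0", {"chest pain"}), "d1": self._sym("d1", set())}
        med = {"d0": self._med("d0", {"aspirin"})}
        cohort, _ = build_cohort(docs, sym, med, ["chest pain"])
        assert cohort[0].symptoms == {"chest pain": True}
        assert cohort[0].medications["aspirin"]
        assert not cohort[1].meds_found

    def test_age_group_cutoff(self):
        assert make_record(age=44.9).age_group == "under_45"
        assert make_record(age=45.0).age_group == "over_45"


class TestContingency:
    def test_reference_cohort_counts(self):
        cohort = synthetic_cohort(597, 464, 1567, 711)
        table = contingency(cohort, "chest pain")
        assert (table.a, table.b, table.c, table.d) == (597, 464, 1567, 711)

    def test_outcome_absent_everywhere(self):
        cohort = synthetic_cohort(0, 5, 0, 7)
        table = contingency(cohort, "chest pain")
        assert (table.a, table.b, table.c, table.d) == (0, 5, 0, 7)

    def test_single_woman_with_outcome(self):
        cohort = synthetic_cohort(1, 0, 0, 0)
        table = contingency(cohort, "chest pain")
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 0)

    def test_restricts_to_found(self):
        cohort = synthetic_cohort(3, 2, 4, 1)
        cohort.append(make_record(doc_id="nf", symptoms={"chest pain": False}, symptoms_found=False))
        table = contingency(cohort, "chest pain", symptomatic_only=True)
        assert table.n == 10
        table_all = contingency(cohort, "chest pain", symptomatic_only=False)
        assert table_all.n == 11

    def test_unknown_outcome(self):
        with pytest.raises(CohortError, match="unknown outcome"):
            contingency(synthetic_cohort(1, 1, 1, 1), "levitation")

    def test_medication_outcome_restricted_to_meds_found(self):
        records = [
            make_record(doc_id="m1", medications={"aspirin": True}, meds_found=True),
            make_record(doc_id="m2", medications={"aspirin": False}, meds_found=False),
        ]
        table = contingency(records, "aspirin")
        assert table.n == 1


class TestOddsRatioUnivariate:
    def test_reference_chest_pain(self):
        result = odds_ratio_univariate(ContingencyTable2x2(597, 464, 1567, 711))
        assert round(result.or_point, 2) == 0.58
        assert round(result.ci_low, 1) == 0.5
        assert round(result.ci_high, 2) == 0.68
        assert result.p_value < 0.001

    def test_symmetric_table(self):
        result = odds_ratio_univariate(ContingencyTable2x2(10, 10, 10, 10))
        assert result.or_point == pytest.approx(1.0)

    def test_closed_form(self):
        result = odds_ratio_univariate(ContingencyTable2x2(2, 8, 4, 6))
        assert result.or_point == pytest.approx(0.375)

    def test_zero_cell_omitted(self):
        result = odds_ratio_univariate(ContingencyTable2x2(0, 1061, 4, 2274))
        assert result.omitted
        assert result.or_point is None
        assert result.omitted_reason == "zero cell"

    @given(cells, cells, cells, cells)
    def test_reciprocity(self, a, b, c, d):
        fwd = odds_ratio_univariate(ContingencyTable2x2(a, b, c, d))
        rev = odds_ratio_univariate(ContingencyTable2x2(c, d, a, b))
        assert fwd.or_point * rev.or_point == pytest.approx(1.0, abs=1e-12)

    @given(cells, cells, cells, cells, st.integers(min_value=2, max_value=9))
    def test_row_scaling_invariance(self, a, b, c, d, k):
        base = odds_ratio_univariate(ContingencyTable2x2(a, b, c, d))
        scaled = odds_ratio_univariate(ContingencyTable2x2(a * k, b * k, c, d))
        assert scaled.or_point == pytest.approx(base.or_point)

    @given(cells, cells, cells, cells)
    def test_woolf_ci_log_symmetric(self, a, b, c, d):
        result = odds_ratio_univariate(ContingencyTable2x2(a, b, c, d))
        assert math.log(result.ci_low) + math.log(result.ci_high) == pytest.approx(
            2 * math.log(result.or_point), abs=1e-9
        )
        assert result.ci_low <= result.or_point <= result.ci_high

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


def brute_force_chi2(table):
    obs = [[table.a, table.b], [table.c, table.d]]
    n = table.n
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = sum(obs[i]) * (obs[0][j] + obs[1][j]) / n
            stat += (obs[i][j] - expected) ** 2 / expected
    return stat


class TestChiSquare:
    def test_no_association(self):
        stat, p = chi_square(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_reference_chest_pain(self):
        _, p = chi_square(ContingencyTable2x2(597, 464, 1567, 711))
        assert p < 0.001

    def test_complete_separation(self):
        table = ContingencyTable2x2(50, 0, 0, 50)
        stat, p = chi_square(table)
        assert stat == pytest.approx(brute_force_chi2(table))
        assert stat == pytest.approx(100.0)
        assert p < 1e-20

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            stat, p = chi_square(ContingencyTable2x2(0, 5, 0, 7))
        assert p is None
        assert math.isnan(stat)

    def test_brute_force_equality_random_tables(self):
        rng = random.Random(42)
        for _ in range(1000):
            table = ContingencyTable2x2(*(rng.randint(1, 50) for _ in range(4)))
            stat, _ = chi_square(table)
            assert stat == pytest.approx(brute_force_chi2(table), rel=1e-10)


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.03 < rejections / n_reps < 0.07


class TestOddsRatioAdjusted:
    def test_reduces_to_univariate_with_constant_covariates(self):
        cohort = []
        for gender, n_with, n_without in (("woman", 30, 20), ("man", 25, 35)):
            for has in [True] * n_with + [False] * n_without:
                cohort.append(
                    make_record(
                        doc_id=f"p{len(cohort)}",
                        gender=gender,
                        symptoms={"chest pain": has},
                    )
                )
        uni = odds_ratio_univariate(contingency(cohort, "chest pain"))
        adj = odds_ratio_adjusted(cohort, "chest pain", ["diabetes", "pci"])
        assert not adj.omitted
        assert round(adj.or_point, 6) == round(uni.or_point, 6)

    def test_degenerate_outcome(self):
        cohort = synthetic_cohort(0, 10, 0, 10)
        result = odds_ratio_adjusted(cohort, "chest pain", ["diabetes"])
        assert result.omitted
        assert result.omitted_reason == "degenerate outcome"

    def test_separation_omitted(self):
        # outcome perfectly determined by gender: infinite MLE
        cohort = synthetic_cohort(20, 0, 0, 20)
        result = odds_ratio_adjusted(cohort, "chest pain", ["diabetes"])
        assert result.omitted

    def test_unknown_covariate(self):
        with pytest.raises(CohortError, match="unknown covariates"):
            odds_ratio_adjusted(synthetic_cohort(5, 5, 5, 5), "chest pain", ["bmi"])

    def test_ci_brackets_point(self):
        cohort = synthetic_cohort(60, 40, 45, 55)
        result = odds_ratio_adjusted(cohort, "chest pain", ["diabetes", "age_group"])
        assert result.ci_low <= result.or_point <= result.ci_high

    def test_parameter_recovery(self):
        """Known gender log-odds effect is recovered within its own CI ~95%
        of the time (quick 50-replicate version)."""
        rng = np.random.default_rng(7)
        true_or = 1.5
        beta = math.log(true_or)
        covered = 0
        n_reps = 50
        for _ in range(n_reps):
            n = 2000
            woman = rng.random(n) < 0.4
            diabetes = rng.random(n) < 0.3
            age = rng.normal(60, 10, n)
            logit = -0.5 + beta * woman
            prob = 1 / (1 + np.exp(-logit))
            y = rng.random(n) < prob
            cohort = [
                make_record(
                    doc_id=f"p{i}",
                    gender="woman" if woman[i] else "man",
                    age=float(age[i]),
                    diabetes=bool(diabetes[i]),
                    symptoms={"chest pain": bool(y[i])},
                )
                for i in range(n)
            ]
            result = odds_ratio_adjusted(cohort, "chest pain", ["diabetes", "age_group"])
            assert not result.omitted
            covered += result.ci_low <= true_or <= result.ci_high
        assert covered / n_reps > 0.85


class TestRenderTables:
    def _cohort(self):
        rng = random.Random(1)
        names = ["chest pain", "weakness", "swelling"]
        records = []
        for i in range(200):
            gender = "woman" if rng.random() < 0.4 else "man"
            records.append(
                make_record(
                    doc_id=f"p{i}",
                    gender=gender,
                    age=rng.uniform(30, 85),
                    diabetes=rng.random() < 0.3,
                    pci=rng.random() < 0.5,
                    symptoms={n: rng.random() < 0.4 for n in names},
                    medications={"aspirin": rng.random() < 0.8},
                )
            )
        return records

    def test_row_per_symptom_sorted(self):
        freq, adj, med = render_tables(self._cohort())
        assert len(freq) == 3
        assert len(adj) == 3
        assert list(freq["total_n"]) == sorted(freq["total_n"], reverse=True)

    def test_full_lexicon_gives_18_rows(self, lexicon):
        rng = random.Random(3)
        names = [c.canonical_name for c in lexicon]
        cohort = [
            make_record(
                doc_id=f"p{i}",
                gender="woman" if i % 3 == 0 else "man",
                symptoms={n: rng.random() < 0.3 for n in names},
            )
            for i in range(150)
        ]
        freq, adj, _ = render_tables(cohort)
        assert len(freq) == 18
        assert len(adj) == 18

    def test_empty_cohort_headers_only(self):
        freq, adj, med = render_tables([])
        assert len(freq) == 0
        assert list(freq.columns)[0] == "symptom"
        assert len(med) == 9  # drug classes always enumerated

    def test_medication_table_single_nonzero_row(self):
        cohort = [
            make_record(
                doc_id=f"p{i}",
                gender="woman" if i % 2 else "man",
                symptoms={"chest pain": False},
                medications={"aspirin": i % 3 != 0},
            )
            for i in range(60)
        ]
        _, _, med = render_tables(cohort)
        nonzero = med[med["total_n"] > 0]
        assert list(nonzero["drug_class"]) == ["aspirin"]
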
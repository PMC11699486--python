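import pytest
from hypothesis import HealthCheck, settings

from cardext.docparse import DischargeSummary
from cardext.lexicon import load_medication_dictionary, load_symptom_lexicon

settings.register_profile(
    "default", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return load_symptom_lexicon()


@pytest.fixture(scope="session")
def dictionary():
    return load_medication_dictionary()


def make_doc(text, doc_id="d1", gender="woman", age=60.0, year=2015,
             diabetes=False, pci=False):
    return DischargeSummary(
        doc_id=doc_id,
        text=text,
        gender=gender,
        age_years=age,
        admission_year=year,
        diabetes=diabetes,
        pci=pci,
    )


@pytest.fixture
def doc_factory():
    return make_doc


def dp_levenshtein(a, b):
    """Independent full-matrix edit-distance oracle for the fuzzy matcher."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]
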
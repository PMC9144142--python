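from pathlib import Path

import numpy as np
import pytest

import psnfuse as pf

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture
def static4( ) -> pf.StaticCohort:
    """Committed 12-patient, 4-class line-list style cohort."""
    return pf.read_static_cohort(
        FIXTURES / "static4_cohort.csv",
        {
            "age": "numeric",
            "gender": "categorical",
            "symptoms": "text",
            "additional_information": "text",
            "chronic_disease_binary": "boolean",
            "chronic_disease": "text",
        },
    )


@pytest.fixture
def longitudinal():
    """Committed 12-patient longitudinal cohort: (static profile, visit sequences)."""
    static = pf.read_static_cohort(
        FIXTURES / "longitudinal_static.csv",
        {"age": "numeric", "gender": "categorical", "smoke": "boolean",
         "diab": "boolean", "hypermed": "boolean"},
    )
    seqs = pf.read_visit_table(
        FIXTURES / "longitudinal_visits.csv",
        id_col="id",
        order_col="visit",
        feature_cols=pf.synthetic.VISIT_FEATURES,
    )
    return static, seqs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_similarity(rng: np.random.Generator, n: int, ids=None) -> pf.SimilarityMatrix:
    """Random symmetric nonnegative similarity matrix with unit diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return pf.SimilarityMatrix(m, ids or [f"P{i}" for i in range(n)])
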
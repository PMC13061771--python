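import numpy as np
import pandas as pd
import pytest

from epileptome.data_io import ClinicalTable, ExpressionMatrix
from epileptome.synthetic_data import fixture_clinical_table


@pytest.fixture(scope="session")
def clinical() -> ClinicalTable:
    """The packaged 16-patient clinical table."""
    return fixture_clinical_table()


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples of raw CPM values."""
    df = pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0], [0.5, 0.0, 10.0, 0.2]],
        index=["geneA", "geneB", "geneC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture()
def random_matrix(clinical) -> ExpressionMatrix:
    """50 genes x 16 samples of positive log-normal CPM values, with the
    packaged cohort's sample identifiers."""
    rng = np.random.default_rng(42)
    values = np.exp2(rng.normal(5, 2, size=(50, 16)))
    df = pd.DataFrame(
        values,
        index=[f"G{i:03d}" for i in range(50)],
        columns=clinical.sample_ids,
    )
    return ExpressionMatrix(df)
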
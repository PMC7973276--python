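import numpy as np
import pandas as pd
import pytest

from immunomark.cohort import Cohort, SampleRecord, SurvivalValue
from immunomark.synthesize import generate_cohort, study_shaped_fixture


def make_two_group_cohort(values_by_analyte: dict[str, np.ndarray],
                          n_long: int, n_short: int,
                          kind: str = "gene_tpm") -> Cohort:
    """Cohort with n_long 'long' then n_short 'short' samples."""
    ids = [f"L{i:02d}" for i in range(n_long)] + [f"S{i:02d}" for i in range(n_short)]
    groups = ["long"] * n_long + ["short"] * n_short
    records = [
        SampleRecord(sid, g, pfs=SurvivalValue(60.0 if g == "long" else 6.0),
                     os=SurvivalValue(70.0 if g == "long" else 12.0))
        for sid, g in zip(ids, groups)
    ]
    matrix = pd.DataFrame(values_by_analyte, index=ids)
    matrix.index.name = "sample_id"
    kinds = {a: kind for a in values_by_analyte}
    return Cohort(records, matrix, kinds)


@pytest.fixture(scope="session")
def fixture_cohort():
    """Study-shaped 26-sample synthetic cohort (fixed seed)."""
    return generate_cohort(study_shaped_fixture(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
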
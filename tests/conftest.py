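import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from synscore import (
    ClinicalTable,
    ExpressionMatrix,
    SyntheticCohortConfig,
    simulate_cohorts,
    simulate_term_collection,
)

#: small-but-realistic cohort used by many integration tests
TINY = SyntheticCohortConfig(
    n_samples=120, n_genes=300, n_terms=12, n_normal=15, term_size_range=(12, 30)
)


@pytest.fixture(scope="session")
def tiny_cohorts():
    """Two simulated batches (expression, clinical) plus ground truth."""
    cohorts, truth = simulate_cohorts(TINY, seed=42)
    return cohorts, truth


@pytest.fixture(scope="session")
def tiny_terms(tiny_cohorts):
    _, truth = tiny_cohorts
    return simulate_term_collection(TINY, truth, seed=42)


def make_expression(values, genes=None, samples=None, **kw) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), **kw)


def make_clinical(os_time, os_event, sample_ids=None, **columns) -> ClinicalTable:
    sample_ids = sample_ids or [f"s{j}" for j in range(len(os_time))]
    df = pd.DataFrame(
        {"os_time": os_time, "os_event": os_event, **columns},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(df)
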
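import numpy as np
import pandas as pd
import pytest

from immunorank.core_io import ClinicalTable, ExpressionMatrix, GeneId


def make_matrix(values, samples=None, gene_keys=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array with generated identifiers."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    gene_keys = gene_keys or [f"g{i}|{i + 1}" for i in range(n_genes)]
    return ExpressionMatrix(
        genes=[GeneId.from_key(k) for k in gene_keys],
        values=pd.DataFrame(arr, index=gene_keys, columns=samples),
    )


def make_clinical(times, events, samples=None) -> ClinicalTable:
    samples = samples or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"survival_years": times, "event": events, "stage": None}, index=samples
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic four-subtype cohort shared across tests."""
    from immunorank.synthetic import generate_cohort

    return generate_cohort(n_samples=120, n_genes=120, noise_sd=0.4, seed=7)


@pytest.fixture(scope="session")
def signature_cohort():
    from immunorank.synthetic import generate_signature_cohort

    return generate_signature_cohort(n_samples=120, coupling=0.9, seed=11)
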
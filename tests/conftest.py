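import numpy as np
import pandas as pd
import pytest

from susgwas.genotype_io import GenotypeData, PHENO_CASE, PHENO_CONTROL, PHENO_MISSING
from susgwas.synthetic_data import (
    SimConfig,
    simulate_case_control_study,
    simulate_unrelated_panel,
)


def make_dataset(calls, chrom=None, bp=None, phenotype=None, a1="A", a2="G"):
    """Small GenotypeData from a call matrix, with sensible defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp": [f"M{j+1}" for j in range(m)],
            "cm": 0.0,
            "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = pd.DataFrame(
        {
            "fid": "F",
            "iid": [f"S{i+1}" for i in range(n)],
            "father": "0",
            "mother": "0",
            "sex": 1,
            "phenotype": phenotype if phenotype is not None else PHENO_MISSING,
        }
    )
    return GenotypeData(calls=calls, markers=markers, samples=samples)


@pytest.fixture(scope="session")
def study():
    """One default ascertained case/control study (35 cases / 18 controls)."""
    return simulate_case_control_study(seed=123)


@pytest.fixture(scope="session")
def null_panel():
    """Unstructured null panel: unrelated samples, random labels."""
    return simulate_unrelated_panel(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
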
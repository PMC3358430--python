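import numpy as np
import pandas as pd
import pytest

from crossqtl.simcohort import simulate_covariates, simulate_genotypes
from crossqtl.types import CohortSpec


@pytest.fixture(scope="session")
def small_cohort():
    """200 samples x 300 SNPs, clean (no planted relateds/outliers)."""
    spec = CohortSpec(200, 300, maf_range=(0.1, 0.5), seed=42)
    dosages, sample_info = simulate_genotypes(spec)
    return dosages, sample_info


@pytest.fixture(scope="session")
def covariates200():
    return simulate_covariates(200, seed=43)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def snp_table():
    """Hand-built SNP records covering each QC filter branch."""
    return pd.DataFrame(
        [
            # snp_id, call_rate, maf, hwe_p, imputed, rsq, expected reasons
            ("clean", 0.96, 0.05, 0.5, False, np.nan, ""),
            ("lowcall", 0.94, 0.05, 0.5, False, np.nan, "callrate"),
            ("rare", 0.99, 0.009, 0.5, False, np.nan, "maf"),
            ("hwefail", 0.99, 0.3, 5e-8, False, np.nan, "hwe"),
            ("imp_ok", 1.0, 0.05, 0.5, True, 0.31, ""),
            ("imp_rsq", 1.0, 0.05, 0.5, True, 0.29, "rsq"),
            ("imp_rare", 1.0, 0.005, 0.5, True, 0.9, "maf"),
            ("broken", np.nan, 0.05, 0.5, False, np.nan, "malformed"),
        ],
        columns=[
            "snp_id", "call_rate", "maf", "hwe_p", "imputed",
            "imputation_rsq", "expected_reasons",
        ],
    )
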